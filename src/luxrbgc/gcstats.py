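"""GC-content anomaly of cluster regions against the genome background.

A cluster region whose base composition deviates from its host genome is a
candidate horizontal-transfer acquisition.  The region is summarized by a
sliding-window GC track (max / mean / min) and compared with background
windows by a z-test on the mean window GC.  The choice of test is this
package's own: the windows are treated as i.i.d. draws from the background
window-GC distribution, so callers wanting a calibrated p-value should use
non-overlapping windows (step = window).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

from .records import NUCLEOTIDES


def gc_content(seq: str) -> float:
    """GC fraction of a nucleotide sequence; N is ignored entirely.

    Returns ``nan`` when the effective (non-N) length is zero.
    """
    bad = set(seq) - NUCLEOTIDES
    if bad:
        raise ValueError(f"illegal nucleotide(s) {sorted(bad)!r}")
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        return float("nan")
    return gc / (gc + at)


def window_gc(seq: str, window: int, step: int) -> list[tuple[int, int, float]]:
    """GC fraction in half-open windows [i, i+window) at the given stride.

    A trailing partial window is kept only when it is longer than half a
    window (an exactly-half tail is already covered by the last full
    window at step = window/2).  A window longer than the sequence
    degrades to a single whole-sequence window.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if window > len(seq):
        return [(0, len(seq), gc_content(seq))]
    out = []
    i = 0
    while i + window <= len(seq):
        out.append((i, i + window, gc_content(seq[i : i + window])))
        i += step
    if i < len(seq) and len(seq) - i > window / 2:
        out.append((i, len(seq), gc_content(seq[i:])))
    return out


@dataclass
class GCProfile:
    """Windowed GC summary of one region plus its anomaly statistics."""

    windows: list[tuple[int, int, float]]
    region_max: float
    region_mean: float
    region_min: float
    genome_mean: Optional[float] = None
    genome_sd: Optional[float] = None
    z: Optional[float] = None
    p_value: Optional[float] = None
    anomalous: Optional[bool] = None
    degenerate: bool = False


def region_profile(seq: str, window: int = 500, step: int = 250) -> GCProfile:
    """Windowed GC track of a region with max/mean/min summary."""
    wins = window_gc(seq, window, step)
    values = [gc for _, _, gc in wins if not math.isnan(gc)]
    if not values:
        raise ValueError("region has no informative (non-N) windows")
    return GCProfile(
        windows=wins,
        region_max=max(values),
        region_mean=sum(values) / len(values),
        region_min=min(values),
    )


def gc_anomaly(
    region_windows: Sequence[float],
    genome_windows: Sequence[float],
    alpha: float = 0.05,
) -> tuple[float, float]:
    """z-test of a region's mean window GC against background windows.

    ``z = (region_mean - genome_mean) / (genome_sd / sqrt(n_region))`` with
    a two-sided normal p-value.  Requires >= 5 background windows; a
    zero-variance background raises (degenerate: the test is undefined).
    """
    if len(genome_windows) < 5:
        raise ValueError("need at least 5 genome background windows")
    if not region_windows:
        raise ValueError("region has no windows")
    genome_mean = float(sum(genome_windows) / len(genome_windows))
    genome_sd = float(
        math.sqrt(
            sum((g - genome_mean) ** 2 for g in genome_windows)
            / (len(genome_windows) - 1)
        )
    )
    if genome_sd == 0:
        raise ValueError("degenerate background: zero variance in genome windows")
    region_mean = float(sum(region_windows) / len(region_windows))
    z = (region_mean - genome_mean) / (genome_sd / math.sqrt(len(region_windows)))
    p = 2.0 * stats.norm.sf(abs(z))
    return z, float(min(p, 1.0))


def profile_with_anomaly(
    seq: str,
    genome_windows: Sequence[float],
    window: int = 500,
    step: int = 250,
    alpha: float = 0.05,
) -> GCProfile:
    """Full per-region GC report: track plus anomaly call.

    The displayed track uses the configured (possibly overlapping) stride;
    the test statistic is computed on non-overlapping windows so its null
    calibration holds.
    """
    prof = region_profile(seq, window, step)
    test_windows = [gc for _, _, gc in window_gc(seq, window, window)
                    if not math.isnan(gc)]
    try:
        z, p = gc_anomaly(test_windows, genome_windows, alpha)
    except ValueError:
        prof.degenerate = True
        return prof
    genome_mean = sum(genome_windows) / len(genome_windows)
    genome_sd = math.sqrt(
        sum((g - genome_mean) ** 2 for g in genome_windows) / (len(genome_windows) - 1)
    )
    prof.genome_mean, prof.genome_sd = float(genome_mean), float(genome_sd)
    prof.z, prof.p_value = z, p
    prof.anomalous = p < alpha
    return prof


def binomial_background(genome_gc: float, window: int, n_windows: int = 100):
    """Theoretical background window GCs for a random-composition genome.

    When only a scalar genome GC is known, background windows are modelled
    as binomial: mean ``genome_gc``, sd ``sqrt(gc*(1-gc)/window)``.  Returns
    a deterministic symmetric sample (normal quantiles) with exactly that
    mean and close to that sd, usable wherever empirical windows are.
    """
    sd = math.sqrt(genome_gc * (1.0 - genome_gc) / window)
    qs = [(i + 0.5) / n_windows for i in range(n_windows)]
    return [genome_gc + sd * float(stats.norm.ppf(q)) for q in qs]
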