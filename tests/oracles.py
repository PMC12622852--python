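"""Independent brute-force reference implementations for the scar detectors.

These deliberately take the slow, exhaustive path (position scans, full
sub-run enumeration) so they share no code with the package's detectors.
"""

from __future__ import annotations

import numpy as np

from valkit.features import ArmRegions, FeatureConfig
from valkit.genome import MB, GenomeModel
from valkit.simulate import CopyNumberProfile


def brute_breakpoints(
    profile: CopyNumberProfile,
    genome: GenomeModel,
    region: str = "whole",
    config: FeatureConfig | None = None,
) -> dict[str, int]:
    """Position scan over all adjacent same-arm segment pairs."""
    config = config or FeatureConfig()
    df = profile.segments
    out = {}
    for arm in genome.arms:
        lo, hi = ArmRegions.for_arm(arm, config.f_tel, config.f_cen).window(region)
        rows = sorted(
            (
                (r.start, r.end, r.total_cn, r.minor_cn)
                for r in df.itertuples()
                if r.chrom == arm.chrom and r.start >= arm.start and r.end <= arm.end
            )
        )
        n = 0
        for a, b in zip(rows[:-1], rows[1:]):
            if a[1] == b[0] and (a[2], a[3]) != (b[2], b[3]) and lo <= b[0] < hi:
                n += 1
        out[arm.name] = n
    return out


def brute_size_histogram(
    profile: CopyNumberProfile,
    genome: GenomeModel,
    region: str = "whole",
    config: FeatureConfig | None = None,
):
    """Clipped-length histogram per size bin: (counts, summed lengths)."""
    config = config or FeatureConfig()
    edges = [0.0] + [b * MB for b in config.size_bins_mb] + [float("inf")]
    counts = [0] * (len(edges) - 1)
    lengths = [0] * (len(edges) - 1)
    df = profile.segments
    for arm in genome.arms:
        lo, hi = ArmRegions.for_arm(arm, config.f_tel, config.f_cen).window(region)
        for r in df.itertuples():
            if r.chrom != arm.chrom or r.start < arm.start or r.end > arm.end:
                continue
            clipped = min(r.end, hi) - max(r.start, lo)
            if clipped <= 0:
                continue
            for i in range(len(counts)):
                if edges[i] <= clipped < edges[i + 1]:
                    counts[i] += 1
                    lengths[i] += clipped
    return counts, lengths


def _is_alternating(x) -> bool:
    if len(set(x[0::2])) != 1 or len(set(x[1::2])) != 1:
        return False
    return x[0] != x[1]


def brute_oscillation_chains(values) -> list[int]:
    """All maximal alternating-two-state sub-runs of length >= 3.

    Enumerates every (i, j) window, keeps alternating ones, and discards
    windows contained in a longer alternating window.
    """
    x = list(values)
    n = len(x)
    alternating = [
        (i, j)
        for i in range(n)
        for j in range(i + 3, n + 1)
        if _is_alternating(x[i:j])
    ]
    maximal = [
        (i, j)
        for (i, j) in alternating
        if not any((p <= i and j <= q and (p, q) != (i, j)) for (p, q) in alternating)
    ]
    return sorted(j - i for (i, j) in maximal)


def brute_gloh(
    profile: CopyNumberProfile,
    genome: GenomeModel,
    whole_arm_fraction: float = 0.9,
) -> float:
    """Merge minor=0 runs per arm, drop whole-arm runs, divide by genome size."""
    df = profile.segments
    total = 0
    for arm in genome.arms:
        rows = sorted(
            (
                (r.start, r.end, r.minor_cn)
                for r in df.itertuples()
                if r.chrom == arm.chrom and r.start >= arm.start and r.end <= arm.end
            )
        )
        runs, cur = [], 0
        for s, e, m in rows:
            if m == 0:
                cur += e - s
            elif cur:
                runs.append(cur)
                cur = 0
        if cur:
            runs.append(cur)
        total += sum(r for r in runs if r < whole_arm_fraction * arm.length)
    return total / genome.total_length


def wilson_by_inversion(x: int, n: int, confidence: float = 0.95):
    """Wilson bounds by numeric inversion of the score test (brentq)."""
    from scipy.optimize import brentq
    from scipy.stats import norm

    z = norm.ppf(0.5 + confidence / 2.0)
    p_hat = x / n

    def score_stat(p0):
        return (p_hat - p0) / np.sqrt(p0 * (1 - p0) / n)

    eps = 1e-12
    lower = 0.0 if x == 0 else brentq(
        lambda p0: score_stat(p0) - z, eps, min(p_hat, 1 - eps), xtol=1e-13
    )
    upper = 1.0 if x == n else brentq(
        lambda p0: score_stat(p0) + z, max(p_hat, eps), 1 - eps, xtol=1e-13
    )
    return lower, upper
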