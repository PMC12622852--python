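"""Copy-number scar features: breakpoints, segment sizes, oscillation, gLOH.

Three feature families are extracted genome-wide and within the telomeric and
centromeric portions of each chromosome arm:

* breakpoints per arm — boundaries between adjacent same-arm segments that
  differ in the allele-specific (total, minor) state;
* segment-size spectrum — counts and genome fraction per size bin plus log10
  size moments;
* oscillation patterns — maximal runs of >= 3 consecutive same-arm segments
  whose total copy number alternates between exactly two states.

A genome-wide LOH fraction (gLOH) with whole-arm exclusion is included as a
side statistic. The default schema has 107 named features in a fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import MB, Arm, GenomeModel
from .simulate import CopyNumberProfile

REGIONS = ("whole", "telomeric", "centromeric")

FEATURE_SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class FeatureConfig:
    f_tel: float = 0.2
    f_cen: float = 0.2
    size_bins_mb: tuple[float, ...] = (1.0, 3.0, 10.0, 30.0, 100.0)
    breakpoint_arm_thresholds: tuple[int, ...] = (1, 2, 3, 5, 8, 10)
    chain_thresholds: tuple[int, ...] = (3, 5, 10)
    schema_version: str = FEATURE_SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.f_tel < 0 or self.f_cen < 0 or self.f_tel + self.f_cen > 1:
            raise ValueError("require f_tel >= 0, f_cen >= 0, f_tel + f_cen <= 1")
        if self.schema_version != FEATURE_SCHEMA_VERSION:
            raise ValueError(f"unknown schema version {self.schema_version!r}")


@dataclass
class FeatureVector:
    """Named numeric scar features in a fixed schema order."""

    values: pd.Series
    schema_version: str = FEATURE_SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.values.isna().any() or not np.isfinite(self.values.values).all():
            raise ValueError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ArmRegions:
    """Telomeric / centromeric / interstitial windows of one arm.

    The telomeric window is the distal fraction ``f_tel`` of the arm, the
    centromeric window the proximal (centromere-side) fraction ``f_cen``; the
    interstitial remainder lies between them. All half-open intervals.
    """

    arm: Arm
    telomeric: tuple[int, int]
    centromeric: tuple[int, int]
    interstitial: tuple[int, int]

    @classmethod
    def for_arm(cls, arm: Arm, f_tel: float, f_cen: float) -> "ArmRegions":
        tel_len = int(round(f_tel * arm.length))
        cen_len = int(round(f_cen * arm.length))
        if arm.arm == "p":  # telomere at start, centromere at end
            tel = (arm.start, arm.start + tel_len)
            cen = (arm.end - cen_len, arm.end)
            mid = (tel[1], cen[0])
        else:  # q: centromere at start, telomere at end
            cen = (arm.start, arm.start + cen_len)
            tel = (arm.end - tel_len, arm.end)
            mid = (cen[1], tel[0])
        return cls(arm, tel, cen, mid)

    def window(self, region: str) -> tuple[int, int]:
        return {
            "whole": (self.arm.start, self.arm.end),
            "telomeric": self.telomeric,
            "centromeric": self.centromeric,
            "interstitial": self.interstitial,
        }[region]


@dataclass(frozen=True)
class _ArmSlice:
    """One arm's segments as plain arrays (sorted by start)."""

    start: np.ndarray
    end: np.ndarray
    total_cn: np.ndarray
    minor_cn: np.ndarray


def _partition_by_arm(profile: CopyNumberProfile, genome: GenomeModel):
    """Split a profile into per-arm array slices, validating the tiling."""
    df = profile.segments.sort_values(["chrom", "start"], kind="mergesort")
    by_chrom = {c: sub for c, sub in df.groupby("chrom", sort=False)}
    out: list[tuple[Arm, _ArmSlice]] = []
    for arm in genome.arms:
        sub = by_chrom.get(arm.chrom)
        if sub is not None:
            starts = sub["start"].values
            mask = (starts >= arm.start) & (sub["end"].values <= arm.end)
            sub = sub[mask]
        if sub is None or len(sub) == 0:
            raise ValueError(f"profile does not tile arm {arm.name}")
        sl = _ArmSlice(
            sub["start"].values, sub["end"].values,
            sub["total_cn"].values, sub["minor_cn"].values,
        )
        if sl.start[0] != arm.start or sl.end[-1] != arm.end:
            raise ValueError(f"profile does not tile arm {arm.name}")
        out.append((arm, sl))
    return out


def _arm_segments(profile: CopyNumberProfile, genome: GenomeModel):
    """Yield (arm, per-arm array slice) for every arm of the genome."""
    yield from _partition_by_arm(profile, genome)


def breakpoints_per_arm(
    profile: CopyNumberProfile,
    genome: GenomeModel,
    region: str = "whole",
    config: FeatureConfig | None = None,
    allele_specific: bool = True,
    parts=None,
) -> dict[str, int]:
    """Count scar breakpoints per arm, optionally restricted to a window.

    A breakpoint is a boundary between adjacent same-arm segments that differ
    in state — the allele-specific (total, minor) pair by default, or total
    copy number only with ``allele_specific=False``. Arm and centromere
    boundaries are never breakpoints. Regional counts keep only boundaries
    whose position falls inside the window.
    """
    config = config or FeatureConfig()
    counts: dict[str, int] = {}
    for arm, sub in parts or _partition_by_arm(profile, genome):
        t = sub.total_cn
        m = sub.minor_cn
        pos = sub.start[1:]  # interior boundaries only
        if allele_specific:
            differ = (t[:-1] != t[1:]) | (m[:-1] != m[1:])
        else:
            differ = t[:-1] != t[1:]
        bps = pos[differ]
        if region != "whole":
            lo, hi = ArmRegions.for_arm(arm, config.f_tel, config.f_cen).window(region)
            bps = bps[(bps >= lo) & (bps < hi)]
        counts[arm.name] = int(len(bps))
    return counts


def segment_size_features(
    profile: CopyNumberProfile,
    genome: GenomeModel,
    region: str = "whole",
    config: FeatureConfig | None = None,
    parts=None,
) -> dict[str, float]:
    """Size-spectrum features: per-bin counts/fractions and log10 moments.

    Regional variants clip each segment to the region window and use the
    clipped lengths; fractions are relative to the region's total length.
    """
    config = config or FeatureConfig()
    sizes = []
    region_total = 0
    for arm, sub in parts or _partition_by_arm(profile, genome):
        lo, hi = ArmRegions.for_arm(arm, config.f_tel, config.f_cen).window(region)
        region_total += hi - lo
        s = np.maximum(sub.start, lo)
        e = np.minimum(sub.end, hi)
        clipped = e - s
        sizes.append(clipped[clipped > 0])
    sizes = np.concatenate(sizes) if sizes else np.array([], dtype=int)
    edges = [0.0] + [b * MB for b in config.size_bins_mb] + [np.inf]
    labels = _size_bin_labels(config)
    out: dict[str, float] = {}
    for (lo_e, hi_e), lab in zip(zip(edges[:-1], edges[1:]), labels):
        in_bin = sizes[(sizes >= lo_e) & (sizes < hi_e)]
        out[f"count_{lab}"] = float(len(in_bin))
        out[f"frac_{lab}"] = float(in_bin.sum() / region_total) if region_total else 0.0
    out["mean_log10_size"] = float(np.mean(np.log10(sizes))) if len(sizes) else 0.0
    out["median_log10_size"] = float(np.median(np.log10(sizes))) if len(sizes) else 0.0
    return out


def _size_bin_labels(config: FeatureConfig) -> list[str]:
    b = [f"{x:g}mb" for x in config.size_bins_mb]
    labels = [f"lt{b[0]}"]
    labels += [f"{b[i]}_{b[i + 1]}" for i in range(len(b) - 1)]
    labels += [f"ge{b[-1]}"]
    return labels


def _alternating_chains(values: np.ndarray, min_len: int = 3) -> list[tuple[int, int]]:
    """Maximal runs of >= min_len entries alternating between two states.

    Returns (start, length) pairs over the input index. Adjacent maximal
    chains may overlap by up to two entries.
    """
    x = values
    n = len(x)
    chains = []
    i = 0
    while i < n - 2:
        if x[i + 1] == x[i]:
            i += 1
            continue
        k = i + 2
        while k < n and x[k] == x[k - 2] and x[k] != x[k - 1]:
            k += 1
        length = k - i
        if length >= min_len:
            chains.append((i, length))
        i = k - 1
    return chains


def oscillation_features(
    profile: CopyNumberProfile,
    genome: GenomeModel,
    region: str = "whole",
    config: FeatureConfig | None = None,
    parts=None,
) -> dict[str, float]:
    """Oscillation features over total-CN alternating chains.

    A chain is a maximal run of >= 3 consecutive same-arm segments whose
    total copy number alternates between exactly two states. Regional
    variants evaluate chains over the contiguous run of segments overlapping
    the window. Returns chain counts at length thresholds, total segments in
    chains, max chain length, and (whole region only) the longest chain per
    chromosome.
    """
    config = config or FeatureConfig()
    all_lengths: list[int] = []
    longest_per_chrom = {c: 0 for c in genome.chrom_names}
    for arm, sub in parts or _partition_by_arm(profile, genome):
        t = sub.total_cn
        if region != "whole":
            lo, hi = ArmRegions.for_arm(arm, config.f_tel, config.f_cen).window(region)
            t = t[(sub.end > lo) & (sub.start < hi)]
        for _, length in _alternating_chains(t):
            all_lengths.append(length)
            if length > longest_per_chrom[arm.chrom]:
                longest_per_chrom[arm.chrom] = length
    lengths = np.array(all_lengths, dtype=int)
    out: dict[str, float] = {}
    for thr in config.chain_thresholds:
        out[f"chains_ge{thr}"] = float((lengths >= thr).sum())
    out["segments_in_chains"] = float(lengths.sum())
    out["max_chain"] = float(lengths.max()) if len(lengths) else 0.0
    if region == "whole":
        for c in genome.chrom_names:
            out[f"longest_chain_{c}"] = float(longest_per_chrom[c])
    return out


def compute_gloh(
    profile: CopyNumberProfile,
    genome: GenomeModel,
    whole_arm_fraction: float = 0.9,
    parts=None,
) -> float:
    """Genome-wide LOH fraction with whole-arm exclusion.

    Adjacent minor_cn = 0 segments on an arm are merged into LOH runs; runs
    spanning >= ``whole_arm_fraction`` of the arm are excluded (whole-arm
    events are not HRD scars). The denominator is the full genome length.
    """
    loh_len = 0
    for arm, sub in parts or _partition_by_arm(profile, genome):
        is_loh = sub.minor_cn == 0
        starts = sub.start
        ends = sub.end
        run_len = 0
        for flag, s, e in zip(is_loh, starts, ends):
            if flag:
                run_len += e - s
            else:
                if 0 < run_len < whole_arm_fraction * arm.length:
                    loh_len += run_len
                run_len = 0
        if 0 < run_len < whole_arm_fraction * arm.length:
            loh_len += run_len
    return loh_len / genome.total_length


def feature_names(genome: GenomeModel, config: FeatureConfig | None = None) -> list[str]:
    """The fixed, ordered feature-name schema for a genome."""
    config = config or FeatureConfig()
    names: list[str] = []
    for region in REGIONS:
        names += [f"bp_{region}_total", f"bp_{region}_mean_arm", f"bp_{region}_max_arm"]
        names += [f"bp_{region}_arms_ge{k}" for k in config.breakpoint_arm_thresholds]
        labels = _size_bin_labels(config)
        for lab in labels:
            names += [f"size_{region}_count_{lab}", f"size_{region}_frac_{lab}"]
        names += [f"size_{region}_mean_log10_size", f"size_{region}_median_log10_size"]
        names += [f"osc_{region}_chains_ge{t}" for t in config.chain_thresholds]
        names += [f"osc_{region}_segments_in_chains", f"osc_{region}_max_chain"]
        if region == "whole":
            names += [f"osc_whole_longest_chain_{c}" for c in genome.chrom_names]
    names.append("gloh")
    return names


def assemble_features(
    profile: CopyNumberProfile,
    genome: GenomeModel,
    config: FeatureConfig | None = None,
) -> FeatureVector:
    """Assemble the full fixed-schema scar feature vector for one profile."""
    config = config or FeatureConfig()
    parts = _partition_by_arm(profile, genome)
    vals: dict[str, float] = {}
    for region in REGIONS:
        bp = breakpoints_per_arm(profile, genome, region, config, parts=parts)
        counts = np.array(list(bp.values()), dtype=float)
        vals[f"bp_{region}_total"] = float(counts.sum())
        vals[f"bp_{region}_mean_arm"] = float(counts.mean())
        vals[f"bp_{region}_max_arm"] = float(counts.max())
        for k in config.breakpoint_arm_thresholds:
            vals[f"bp_{region}_arms_ge{k}"] = float((counts >= k).sum())
        for key, v in segment_size_features(profile, genome, region, config, parts=parts).items():
            vals[f"size_{region}_{key}"] = v
        for key, v in oscillation_features(profile, genome, region, config, parts=parts).items():
            vals[f"osc_{region}_{key}"] = v
    vals["gloh"] = compute_gloh(profile, genome, parts=parts)
    series = pd.Series(vals, dtype=float).reindex(feature_names(genome, config))
    return FeatureVector(series, config.schema_version)


def feature_matrix(
    profiles: dict[str, CopyNumberProfile],
    genome: GenomeModel,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Stack feature vectors for many samples into a samples x features frame."""
    config = config or FeatureConfig()
    rows = {
        sid: assemble_features(p, genome, config).values for sid, p in profiles.items()
    }
    return pd.DataFrame(rows).T.reindex(columns=feature_names(genome, config))
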