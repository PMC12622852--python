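"""Analytical-validation estimators: Wilson CIs, LoB/LoD, concordance,
precision and interference agreement.

Every proportion is reported as a :class:`ProportionWithCI` — an x/n point
estimate with two-sided Wilson score bounds. Replicate-level statistics are
validity-weighted: QC-invalid replicates (and, where noted, replicates with
unknown status) drop out of numerator and denominator alike, so all results
are invariant to replicate ordering and to insertion of invalid replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import norm

from .simulate import ReplicateRecord, SnpVafTable

CONTROL_INTERFERENTS = ("normal_control", "dmso_control")


@dataclass(frozen=True)
class ProportionWithCI:
    """x/n with two-sided Wilson 95% (by default) score bounds."""

    x: int
    n: int
    estimate: float
    lower: float
    upper: float
    confidence: float = 0.95
    method: str = "wilson"

    def __post_init__(self) -> None:
        if not 0 <= self.x <= self.n:
            raise ValueError("require 0 <= x <= n")
        if not (0 <= self.lower <= self.estimate <= self.upper <= 1):
            raise ValueError("require 0 <= lower <= estimate <= upper <= 1")

    def pct(self, what: str = "estimate", ndigits: int = 2) -> float:
        """Percentage rounded half-up to ``ndigits`` (report parity)."""
        return round_half_up(getattr(self, what) * 100.0, ndigits)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 call-vs-truth counts plus unknown-status margins.

    a: call+/truth+, b: call+/truth-, c: call-/truth+, d: call-/truth-.
    """

    a: int
    b: int
    c: int
    d: int
    unknown_pos: int = 0
    unknown_neg: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d, self.unknown_pos, self.unknown_neg) < 0:
            raise ValueError("all counts must be >= 0")


@dataclass
class DilutionLevelSummary:
    """Hit rate and mean adjusted purity at one dilution level of a specimen."""

    specimen_id: str
    level: float
    n_valid: int
    n_hit: int
    hit_rate: ProportionWithCI
    mean_adjusted_tp: float

    def __post_init__(self) -> None:
        if self.n_hit > self.n_valid:
            raise ValueError("n_hit cannot exceed n_valid")


def round_half_up(value: float, ndigits: int = 2) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def wilson_ci(x: int, n: int, confidence: float = 0.95) -> ProportionWithCI:
    """Two-sided Wilson score interval for x successes in n trials.

    Uses the exact normal quantile with no continuity correction; at the
    boundaries the closed form gives lower = 0 for x = 0 and
    lower = n/(n + z^2) for x = n.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= x <= n:
        raise ValueError("require 0 <= x <= n")
    z = norm.ppf(0.5 + confidence / 2.0)
    p = x / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = (z / denom) * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    # guard float round-off at the x=0 / x=n boundaries
    lower = min(max(0.0, center - half), p)
    upper = max(min(1.0, center + half), p)
    return ProportionWithCI(int(x), int(n), p, lower, upper, confidence)


# ---------------------------------------------------------------------------
# replicate-list helpers


def _is_valid(rep: ReplicateRecord) -> bool:
    return bool(rep.qc_valid)


def _known(rep: ReplicateRecord) -> bool:
    return rep.qc_valid and rep.call in ("positive", "negative")


def lob_fpr(replicates: list[ReplicateRecord], confidence: float = 0.95) -> ProportionWithCI:
    """Limit-of-blank false-positive rate: positive calls over valid replicates."""
    valid = [r for r in replicates if _is_valid(r)]
    if not valid:
        raise ValueError("no valid replicates")
    x = sum(1 for r in valid if r.call == "positive")
    return wilson_ci(x, len(valid), confidence)


def dilution_factor(
    vafs_undiluted: SnpVafTable,
    vafs_diluted: SnpVafTable,
    imbalance_threshold: float = 0.02,
    min_snps: int = 50,
) -> float:
    """Dilution factor inferred from the shift of het-SNP VAFs toward 1/2.

    Over het-in-normal SNPs shared by both tables and allele-imbalanced in
    the undiluted specimen (|VAF - 1/2| above both ``imbalance_threshold``
    and four binomial standard errors, to keep balanced SNPs whose deviation
    is pure noise out of the set), the factor is::

        mean(|vaf_diluted - 1/2|) / mean(|vaf_undiluted - 1/2|)

    clamped to [0, 1]. Requires >= ``min_snps`` usable SNPs.
    """
    u = vafs_undiluted.rows
    d = vafs_diluted.rows
    merged = u.merge(
        d, on=["chrom", "pos"], suffixes=("_u", "_d"), how="inner"
    )
    merged = merged[merged["het_in_normal_u"] & merged["het_in_normal_d"]]
    dev_u = (merged["vaf_u"] - 0.5).abs().values
    se = np.sqrt(0.25 / merged["depth_u"].values)
    keep = dev_u > np.maximum(imbalance_threshold, 4.0 * se)
    if keep.sum() < min_snps:
        raise ValueError(
            f"only {int(keep.sum())} usable imbalanced SNPs (need >= {min_snps})"
        )
    dev_d = (merged["vaf_d"] - 0.5).abs().values
    factor = dev_d[keep].mean() / dev_u[keep].mean()
    return float(np.clip(factor, 0.0, 1.0))


def adjusted_tp(undiluted_tp: float, factor: float) -> float:
    """Adjusted tumor purity: undiluted computational purity x dilution factor."""
    if not 0 <= undiluted_tp <= 1 or not 0 <= factor <= 1:
        raise ValueError("inputs must lie in [0, 1]")
    return undiluted_tp * factor


def summarize_dilution_level(
    specimen_id: str,
    level: float,
    replicates: list[ReplicateRecord],
    adjusted_tps: list[float],
) -> DilutionLevelSummary:
    """Hit rate over valid replicates at one level, with mean adjusted TP."""
    valid = [r for r in replicates if _is_valid(r)]
    if not valid:
        raise ValueError(f"no valid replicates at level {level}")
    hits = sum(1 for r in valid if r.call == "positive")
    return DilutionLevelSummary(
        specimen_id=specimen_id,
        level=level,
        n_valid=len(valid),
        n_hit=hits,
        hit_rate=wilson_ci(hits, len(valid)),
        mean_adjusted_tp=float(np.mean(adjusted_tps)) if adjusted_tps else float("nan"),
    )


def determine_lod(
    levels: list[DilutionLevelSummary],
    hit_threshold: float = 0.95,
) -> tuple[dict[str, dict], float]:
    """Per-specimen LoD (lowest level with hit rate >= threshold) and overall.

    The per-specimen LoD value is the mean adjusted tumor purity at the
    lowest passing dilution level; the overall LoD is the median of the
    determined per-specimen values. Specimens with no passing level are
    reported as not determined.
    """
    per_specimen: dict[str, dict] = {}
    by_spec: dict[str, list[DilutionLevelSummary]] = {}
    for lv in levels:
        by_spec.setdefault(lv.specimen_id, []).append(lv)
    for sid, lvs in by_spec.items():
        passing = [lv for lv in sorted(lvs, key=lambda v: v.level) if lv.hit_rate.estimate >= hit_threshold]
        if passing:
            best = passing[0]
            per_specimen[sid] = {
                "level": best.level,
                "adjusted_tp": best.mean_adjusted_tp,
                "determined": True,
            }
        else:
            per_specimen[sid] = {"level": None, "adjusted_tp": None, "determined": False}
    values = [v["adjusted_tp"] for v in per_specimen.values() if v["determined"]]
    if not values:
        raise ValueError("no specimen reached the hit-rate threshold at any level")
    return per_specimen, float(np.median(values))


def concordance_ppa_npa(
    table: ContingencyTable,
    include_unknown_in_npa: bool = False,
    confidence: float = 0.95,
) -> tuple[ProportionWithCI, ProportionWithCI]:
    """PPA = a/(a+c) and NPA = d/(b+d) with Wilson intervals.

    Unknown-status samples are excluded by default; with
    ``include_unknown_in_npa`` the NPA denominator grows to
    b + d + unknown_neg (a conservative sensitivity analysis).
    """
    if table.a + table.c == 0 or table.b + table.d == 0:
        raise ValueError("empty truth margin")
    ppa = wilson_ci(table.a, table.a + table.c, confidence)
    n_npa = table.b + table.d + (table.unknown_neg if include_unknown_in_npa else 0)
    npa = wilson_ci(table.d, n_npa, confidence)
    return ppa, npa


def majority_reference(calls: list[str]) -> str:
    """Majority-call reference: positive iff >= 50% of known calls positive."""
    known = [c for c in calls if c in ("positive", "negative")]
    if not known:
        raise ValueError("no known-status calls")
    frac_pos = sum(1 for c in known if c == "positive") / len(known)
    return "positive" if frac_pos >= 0.5 else "negative"


def _group_by_specimen(replicates: list[ReplicateRecord]):
    groups: dict[str, list[ReplicateRecord]] = {}
    for r in replicates:
        groups.setdefault(r.specimen_id, []).append(r)
    return groups


def reproducibility(
    replicates: list[ReplicateRecord],
) -> tuple[dict[str, ProportionWithCI], dict[str, ProportionWithCI]]:
    """Inter-run agreement with each specimen's majority-call reference.

    Returns (per-specimen, pooled) where pooled has keys "positive" and
    "negative" aggregating specimens by their reference status. Replicates
    that are QC-invalid or have unknown status are excluded from both sums.
    """
    per: dict[str, ProportionWithCI] = {}
    pooled_counts = {"positive": [0, 0], "negative": [0, 0]}
    for sid, reps in _group_by_specimen(replicates).items():
        known = [r for r in reps if _known(r)]
        if not known:
            raise ValueError(f"specimen {sid} has no valid known-status replicates")
        ref = majority_reference([r.call for r in known])
        agree = sum(1 for r in known if r.call == ref)
        per[sid] = wilson_ci(agree, len(known))
        pooled_counts[ref][0] += agree
        pooled_counts[ref][1] += len(known)
    pooled = {
        status: wilson_ci(x, n)
        for status, (x, n) in pooled_counts.items()
        if n > 0
    }
    return per, pooled


def repeatability(replicates: list[ReplicateRecord]) -> ProportionWithCI:
    """Within-run pair agreement: both replicates of a run valid and equal.

    Replicate pairs are keyed by (specimen, site, reagent lot, sequencer/run,
    plate); pairs with any invalid or unknown-status member are excluded from
    numerator and denominator.
    """
    pairs: dict[tuple, list[ReplicateRecord]] = {}
    for r in replicates:
        key = (r.specimen_id, r.site, r.reagent_lot, r.sequencer_or_run, r.plate)
        pairs.setdefault(key, []).append(r)
    agree = total = 0
    for key, members in pairs.items():
        if len(members) != 2:
            if len(members) > 2:
                raise ValueError(f"run {key} carries more than 2 replicates")
            continue
        if not all(_known(m) for m in members):
            continue
        total += 1
        if members[0].call == members[1].call:
            agree += 1
    if total == 0:
        raise ValueError("no complete valid replicate pairs")
    return wilson_ci(agree, total)


def interference_agreement(
    replicates: list[ReplicateRecord],
) -> tuple[pd.DataFrame, ProportionWithCI]:
    """Percent agreement per (specimen, substance) and overall.

    Each specimen's reference status is the majority call over its
    control-condition replicates (normal/vehicle controls). Specimens without
    any known-status control replicate (e.g. necrosis-only samples) fall back
    to the majority over all their replicates for the sample-level figure and
    are excluded from the overall aggregate.
    """
    rows = []
    overall_agree = overall_n = 0
    for sid, reps in _group_by_specimen(replicates).items():
        control_calls = [
            r.call for r in reps if _known(r) and r.interferent in CONTROL_INTERFERENTS
        ]
        has_reference = len(control_calls) > 0
        if has_reference:
            ref = majority_reference(control_calls)
        else:
            known = [r.call for r in reps if _known(r)]
            if not known:
                raise ValueError(f"specimen {sid} has no valid replicates")
            ref = majority_reference(known)
        by_substance: dict[str, list[ReplicateRecord]] = {}
        for r in reps:
            by_substance.setdefault(r.interferent or "none", []).append(r)
        for substance, group in sorted(by_substance.items()):
            known = [r for r in group if _known(r)]
            if not known:
                continue
            agree = sum(1 for r in known if r.call == ref)
            ci = wilson_ci(agree, len(known))
            rows.append(
                {
                    "specimen_id": sid,
                    "interferent": substance,
                    "concentration": group[0].interferent_concentration,
                    "agree": agree,
                    "n_valid": len(known),
                    "pct_agreement": ci.pct(),
                    "included_in_overall": has_reference,
                }
            )
            if has_reference:
                overall_agree += agree
                overall_n += len(known)
    if overall_n == 0:
        raise ValueError("no groups with a determinable control reference")
    return pd.DataFrame(rows), wilson_ci(overall_agree, overall_n)
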