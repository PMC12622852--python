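"""Synthetic copy-number / SNP-VAF data generator for assay validation studies.

Emulates the contrast between HRD-scarred genomes (elevated breakpoint density,
short-segment excess, oscillating copy-number runs, widespread LOH) and quiet,
diploid-dominated HRD-negative genomes, plus the study machinery around them:
matched-normal dilution, factorial replicate cohorts, Bernoulli QC failures and
(null-effect by default) interferent spike-ins.

The simulator emits already-segmented allele-specific truth profiles. What a
replicate "observes" is a re-decoded integer profile: per-segment log-ratio and
allele-imbalance signals are attenuated by tumor purity, perturbed by Gaussian
noise, and inverted back to integer copy numbers with the purity known — so
decoding error grows like ``noise_sd / purity`` and calls degrade gracefully as
specimens are diluted, without any read-level simulation.

For a heterozygous SNP inside a segment with total copy number ``t`` and minor
copy number ``m``, the expected VAF of the allele on the minor haplotype at
tumor purity ``rho`` is::

    E[VAF] = (rho * m + (1 - rho)) / (rho * t + 2 * (1 - rho))

which reduces to 1/2 at ``rho = 0`` and to ``m / t`` at ``rho = 1``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import MB, GenomeModel

PROFILE_COLUMNS = ["chrom", "start", "end", "total_cn", "minor_cn"]
VAF_COLUMNS = ["chrom", "pos", "vaf", "depth", "het_in_normal"]

STUDY_TYPES = ("LOB", "LOD", "CONCORDANCE", "PRECISION", "INTERFERENCE")

#: Interferents assessed by the validation design. All default effects are
#: null (no measurable impact); non-null hooks exist for robustness testing.
DEFAULT_INTERFERENT_EFFECTS: dict[str, dict] = {
    name: {"depth_factor": 1.0, "extra_noise_sd": 0.0}
    for name in (
        "melanin",
        "proteinase_k",
        "molecular_index_barcodes",
        "ethanol",
        "hemoglobin",
        "triglycerides",
        "xylene",
        "conjugated_bilirubin",
        "unconjugated_bilirubin",
        "necrotic",
        "normal_control",
        "dmso_control",
    )
}


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ScarParams:
    """Generator knobs quantifying the scarred-vs-quiet genome contrast.

    Rates are expected breakpoints per 100 Mb per arm; oscillation bursts are
    expected events per genome (positives only); ``short_segment_bias_pos`` is
    the probability that a breakpoint in a positive genome spawns a companion
    breakpoint <10 Mb downstream; LOH fractions target the genome fraction
    with minor copy number 0.
    """

    breakpoint_rate_pos: float = 10.0
    breakpoint_rate_neg: float = 1.5
    oscillation_burst_rate_pos: float = 6.0
    oscillation_len_range: tuple[int, int] = (4, 10)
    short_segment_bias_pos: float = 0.5
    loh_fraction_pos: float = 0.35
    loh_fraction_neg: float = 0.05
    cn_state_range: tuple[int, int] = (1, 5)
    noise_sd: float = 0.02
    snp_density: float = 1.0  # SNPs per Mb
    depth: float = 500.0  # mean read depth
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "breakpoint_rate_pos",
            "breakpoint_rate_neg",
            "oscillation_burst_rate_pos",
            "short_segment_bias_pos",
            "loh_fraction_pos",
            "loh_fraction_neg",
            "noise_sd",
            "snp_density",
            "depth",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.breakpoint_rate_pos <= self.breakpoint_rate_neg:
            raise ValueError("breakpoint_rate_pos must exceed breakpoint_rate_neg")
        if self.cn_state_range[0] < 0 or self.cn_state_range[0] > self.cn_state_range[1]:
            raise ValueError("invalid cn_state_range")


@dataclass
class CopyNumberProfile:
    """Ordered allele-specific integer copy-number segments tiling a genome.

    ``segments`` columns: chrom, start, end (0-based half-open), total_cn,
    minor_cn (the lesser allele count).
    """

    segments: pd.DataFrame

    def __post_init__(self) -> None:
        self.segments = self.segments.reset_index(drop=True)[PROFILE_COLUMNS]

    def validate(self, genome: GenomeModel) -> None:
        """Assert the tiling/ordering/maximality invariants against a genome."""
        df = self.segments
        if (df["total_cn"] < 0).any() or (df["minor_cn"] < 0).any():
            raise ValueError("copy numbers must be >= 0")
        if (df["minor_cn"] > df["total_cn"] - df["minor_cn"]).any():
            raise ValueError("minor_cn must be the lesser allele count")
        for arm in genome.arms:
            sub = df[
                (df["chrom"] == arm.chrom)
                & (df["start"] >= arm.start)
                & (df["end"] <= arm.end)
            ].sort_values("start")
            if len(sub) == 0:
                raise ValueError(f"arm {arm.name} not covered")
            if sub["start"].iloc[0] != arm.start or sub["end"].iloc[-1] != arm.end:
                raise ValueError(f"arm {arm.name} not tiled exactly")
            if not (sub["end"].values[:-1] == sub["start"].values[1:]).all():
                raise ValueError(f"gap/overlap within arm {arm.name}")
            same = (sub["total_cn"].values[:-1] == sub["total_cn"].values[1:]) & (
                sub["minor_cn"].values[:-1] == sub["minor_cn"].values[1:]
            )
            if same.any():
                raise ValueError(f"non-maximal segmentation on arm {arm.name}")
        covered = int((df["end"] - df["start"]).sum())
        if covered != genome.total_length:
            raise ValueError("segments do not tile the genome")

    def copy(self) -> "CopyNumberProfile":
        return CopyNumberProfile(self.segments.copy())


@dataclass
class SnpVafTable:
    """Heterozygous-SNP variant allele frequencies with read depths."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        self.rows = self.rows.reset_index(drop=True)[VAF_COLUMNS]
        df = self.rows
        if (df["depth"] <= 0).any():
            raise ValueError("depth must be > 0")
        if ((df["vaf"] < 0) | (df["vaf"] > 1)).any():
            raise ValueError("vaf must lie in [0, 1]")
        for _, sub in df.groupby("chrom", sort=False):
            if not np.all(np.diff(sub["pos"].values) > 0):
                raise ValueError("positions must be strictly increasing per chrom")


@dataclass
class Specimen:
    """One source specimen with fixed ground truth and its undiluted data."""

    specimen_id: str
    disease_label: str
    hrd_truth: str  # "positive" | "negative"
    biomarker_truth: str  # "LOF_REV" | "HRR_wildtype" | "HRR_altered_other"
    purity: float
    profile: CopyNumberProfile
    vafs: SnpVafTable

    def __post_init__(self) -> None:
        if not 0 <= self.purity <= 1:
            raise ValueError("purity must lie in [0, 1]")


@dataclass
class ReplicateRecord:
    """One assay replicate within a validation study."""

    replicate_id: str
    specimen_id: str
    study: str
    site: int = 1
    reagent_lot: int = 1
    sequencer_or_run: int = 1
    plate: int = 1
    rep_k: int = 1
    dilution_level: float | None = None
    interferent: str | None = None
    interferent_concentration: str | None = None
    qc_valid: bool = True
    qc_fail_stage: str | None = None
    effective_purity: float = 1.0
    observed_profile: CopyNumberProfile | None = None
    observed_vafs: SnpVafTable | None = None
    score: float | None = None
    call: str | None = None  # "positive" | "negative" | "unknown"
    call_reason: str | None = None


# ---------------------------------------------------------------------------
# core generative model


def expected_vaf(total_cn, minor_cn, purity):
    """Expected het-SNP VAF of the minor-haplotype allele at a given purity."""
    t = np.asarray(total_cn, dtype=float)
    m = np.asarray(minor_cn, dtype=float)
    denom = purity * t + 2.0 * (1.0 - purity)
    return (purity * m + (1.0 - purity)) / denom


def _draw_state(rng, cn_range, loh_fraction, forbid=None):
    """Draw a (total, minor) state; LOH status first, then total CN.

    Total CN is weighted toward the diploid state; non-LOH segments need
    total >= 2 so a balanced minor allele exists.
    """
    lo, hi = cn_range
    states = np.arange(max(lo, 0), hi + 1)
    weights = np.exp(-1.2 * np.abs(states - 2.0))
    for _ in range(50):
        if rng.random() < loh_fraction:
            t = int(rng.choice(states, p=weights / weights.sum()))
            m = 0
        else:
            ok = states >= 2
            t = int(rng.choice(states[ok], p=weights[ok] / weights[ok].sum()))
            m = int(rng.integers(1, t // 2 + 1))
        if forbid is None or (t, m) != forbid:
            return t, m
    # fall back to a guaranteed-different total
    t = forbid[0] + 1 if forbid[0] < hi else forbid[0] - 1
    return max(t, 0), min(forbid[1], max(t, 0) // 2)


def _simulate_arm_segments(rng, arm, hrd_truth, params: ScarParams):
    """Breakpoint placement + state assignment for one arm; returns row list."""
    if hrd_truth == "blank":
        return [(arm.chrom, arm.start, arm.end, 2, 1)]
    positive = hrd_truth == "positive"
    rate = params.breakpoint_rate_pos if positive else params.breakpoint_rate_neg
    lam = rate * arm.length / (100 * MB)
    k = int(rng.poisson(lam))
    pts = list(rng.integers(arm.start + 1, arm.end, size=k))
    if positive and params.short_segment_bias_pos > 0:
        for p in list(pts):
            if rng.random() < params.short_segment_bias_pos:
                q = p + int(rng.uniform(0.3 * MB, 8 * MB))
                if q < arm.end:
                    pts.append(q)
    bounds = [arm.start] + sorted(set(int(p) for p in pts)) + [arm.end]
    bounds = sorted(set(bounds))
    loh = params.loh_fraction_pos if positive else params.loh_fraction_neg
    rows = []
    prev = None
    for s, e in zip(bounds[:-1], bounds[1:]):
        t, m = _draw_state(rng, params.cn_state_range, loh, forbid=prev)
        rows.append((arm.chrom, s, e, t, m))
        prev = (t, m)
    return rows


def _insert_oscillation_bursts(rng, rows_by_arm, params: ScarParams):
    """Carve alternating (t, t+1) runs into randomly chosen host segments."""
    n_bursts = int(rng.poisson(params.oscillation_burst_rate_pos))
    lo, hi = params.oscillation_len_range
    arm_keys = list(rows_by_arm)
    for _ in range(n_bursts):
        length = int(rng.integers(lo, hi + 1))
        if length % 2 == 0:
            length += 1  # odd inner run -> both flanks keep the host state
        seg_lens = (rng.uniform(0.2 * MB, 2.0 * MB, size=length)).astype(int)
        need = int(seg_lens.sum()) + 2
        # pick a host segment large enough, length-weighted
        candidates = []
        for key in arm_keys:
            for i, (c, s, e, t, m) in enumerate(rows_by_arm[key]):
                if e - s > need:
                    candidates.append((key, i, e - s))
        if not candidates:
            continue
        w = np.array([c[2] for c in candidates], dtype=float)
        key, i, _ = candidates[rng.choice(len(candidates), p=w / w.sum())]
        c, s, e, t, m = rows_by_arm[key][i]
        hi_cn = params.cn_state_range[1]
        alt = t + 1 if t + 1 <= hi_cn + 1 else t - 1
        istart = int(rng.integers(s + 1, e - need + 1))
        burst = []
        pos = istart
        for j, L in enumerate(seg_lens):
            tt = alt if j % 2 == 0 else t
            mm = min(m, tt // 2)
            if tt == alt:
                mm = min(m, alt // 2)
            burst.append((c, pos, pos + int(L), tt, mm))
            pos += int(L)
        new = [(c, s, istart, t, m)] + burst + [(c, pos, e, t, m)]
        rows_by_arm[key] = rows_by_arm[key][:i] + new + rows_by_arm[key][i + 1 :]
    return rows_by_arm


def _merge_adjacent(df: pd.DataFrame) -> pd.DataFrame:
    """Merge adjacent same-arm segments with identical (total, minor)."""
    out = []
    for _, sub in df.groupby("arm_key", sort=False):
        sub = sub.sort_values("start")
        cur = None
        for row in sub.itertuples(index=False):
            if (
                cur is not None
                and cur[3] == row.total_cn
                and cur[4] == row.minor_cn
                and cur[2] == row.start
            ):
                cur[2] = row.end
            else:
                if cur is not None:
                    out.append(tuple(cur))
                cur = [row.chrom, row.start, row.end, row.total_cn, row.minor_cn]
        if cur is not None:
            out.append(tuple(cur))
    return pd.DataFrame(out, columns=PROFILE_COLUMNS)


def _with_arm_key(df: pd.DataFrame, genome: GenomeModel) -> pd.DataFrame:
    df = df.copy()
    cen = {c.name: c.centromere for c in genome.chromosomes}
    arm = np.where(
        df["start"].values < df["chrom"].map(cen).values, "p", "q"
    )
    df["arm_key"] = df["chrom"].astype(str) + arm
    return df


def simulate_truth_profile(
    genome: GenomeModel, hrd_truth: str, params: ScarParams, rng
) -> CopyNumberProfile:
    """Simulate a maximal allele-specific truth segmentation of the genome."""
    rows_by_arm = {}
    for arm in genome.arms:
        rows_by_arm[arm.name] = _simulate_arm_segments(rng, arm, hrd_truth, params)
    if hrd_truth == "positive" and params.oscillation_burst_rate_pos > 0:
        rows_by_arm = _insert_oscillation_bursts(rng, rows_by_arm, params)
    rows = [r for arm in genome.arms for r in rows_by_arm[arm.name]]
    df = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    df = _merge_adjacent(_with_arm_key(df, genome))
    return CopyNumberProfile(df)


def simulate_snp_positions(genome: GenomeModel, density_per_mb: float, rng):
    """Fixed per-specimen SNP coordinates: (chrom array, pos array)."""
    chroms, positions = [], []
    for c in genome.chromosomes:
        n = int(round(density_per_mb * c.length / MB))
        pos = np.sort(rng.choice(c.length, size=min(n, c.length), replace=False))
        chroms.extend([c.name] * len(pos))
        positions.append(pos)
    return np.array(chroms), np.concatenate(positions) if positions else np.array([], int)


def sample_vafs(
    profile: CopyNumberProfile,
    chroms: np.ndarray,
    positions: np.ndarray,
    purity: float,
    mean_depth: float,
    rng,
) -> SnpVafTable:
    """Draw binomial VAFs at fixed SNP positions for a profile at a purity.

    Each het SNP reports the allele on the minor or major haplotype with equal
    probability; depth is Poisson around ``mean_depth`` (floored at 1).
    """
    seg = profile.segments
    t = np.full(len(positions), 2.0)
    m = np.full(len(positions), 1.0)
    for chrom, sub in seg.groupby("chrom", sort=False):
        mask = chroms == chrom
        if not mask.any():
            continue
        idx = np.searchsorted(sub["start"].values, positions[mask], side="right") - 1
        idx = np.clip(idx, 0, len(sub) - 1)
        t[mask] = sub["total_cn"].values[idx]
        m[mask] = sub["minor_cn"].values[idx]
    on_minor = rng.random(len(positions)) < 0.5
    allele_cn = np.where(on_minor, m, t - m)
    denom = purity * t + 2.0 * (1.0 - purity)
    exp = np.where(denom > 0, (purity * allele_cn + (1.0 - purity)) / np.maximum(denom, 1e-12), 0.5)
    exp = np.clip(exp, 0.0, 1.0)
    depth = np.maximum(rng.poisson(mean_depth, size=len(positions)), 1)
    alt = rng.binomial(depth, exp)
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "vaf": alt / depth,
            "depth": depth,
            "het_in_normal": True,
        }
    )
    return SnpVafTable(df)


def simulate_specimen(
    genome: GenomeModel,
    hrd_truth: str,
    params: ScarParams,
    purity: float,
    seed: int,
    specimen_id: str = "SP0",
    disease_label: str = "breast",
    biomarker_truth: str | None = None,
) -> Specimen:
    """Simulate one specimen: truth profile + undiluted het-SNP VAF table.

    ``hrd_truth`` is "positive", "negative", or "blank" (flat diploid normal
    tissue). Same seed → identical output.
    """
    if not 0 <= purity <= 1:
        raise ValueError("purity must lie in [0, 1]")
    if len(genome.chromosomes) == 0:
        raise ValueError("empty genome")
    if hrd_truth not in ("positive", "negative", "blank"):
        raise ValueError(f"unknown hrd_truth {hrd_truth!r}")
    rng = np.random.default_rng(seed)
    profile = simulate_truth_profile(genome, hrd_truth, params, rng)
    chroms, positions = simulate_snp_positions(genome, params.snp_density, rng)
    vafs = sample_vafs(profile, chroms, positions, purity, params.depth, rng)
    if biomarker_truth is None:
        biomarker_truth = "LOF_REV" if hrd_truth == "positive" else "HRR_wildtype"
    return Specimen(
        specimen_id=specimen_id,
        disease_label=disease_label,
        hrd_truth="negative" if hrd_truth == "blank" else hrd_truth,
        biomarker_truth=biomarker_truth,
        purity=purity,
        profile=profile,
        vafs=vafs,
    )


def decode_observed_profile(
    truth: CopyNumberProfile,
    genome: GenomeModel,
    purity: float,
    noise_sd: float,
    rng,
    cn_max: int = 8,
) -> CopyNumberProfile:
    """Re-decode integer copy numbers from purity-attenuated noisy signals.

    Per segment the implied log-ratio ``log2((rho*t + 2(1-rho))/2)`` and
    allele imbalance ``rho*(t/2 - m) / (rho*t + 2(1-rho))`` are perturbed with
    Gaussian noise (sd ``noise_sd`` and ``noise_sd/2``) and inverted with the
    purity known, so decoding error scales like ``noise_sd / purity``. Below
    2% purity the tumor signal is unresolvable and a flat diploid profile is
    returned.
    """
    if purity < 0.02:
        rows = [(a.chrom, a.start, a.end, 2, 1) for a in genome.arms]
        df = _merge_adjacent(_with_arm_key(pd.DataFrame(rows, columns=PROFILE_COLUMNS), genome))
        return CopyNumberProfile(df)
    seg = truth.segments
    t = seg["total_cn"].values.astype(float)
    m = seg["minor_cn"].values.astype(float)
    denom = purity * t + 2.0 * (1.0 - purity)
    lr = np.log2(np.maximum(denom, 1e-6) / 2.0) + rng.normal(0, noise_sd, len(seg))
    t_hat = np.rint((2.0 * 2.0**lr - 2.0 * (1.0 - purity)) / purity)
    t_hat = np.clip(t_hat, 0, cn_max).astype(int)
    ai = purity * (t / 2.0 - m) / np.maximum(denom, 1e-6)
    ai_obs = ai + rng.normal(0, noise_sd / 2.0, len(seg))
    dh = purity * t_hat + 2.0 * (1.0 - purity)
    m_hat = np.rint(t_hat / 2.0 - ai_obs * dh / purity)
    m_hat = np.clip(m_hat, 0, t_hat // 2).astype(int)
    df = seg.copy()
    df["total_cn"] = t_hat
    df["minor_cn"] = m_hat
    df = _merge_adjacent(_with_arm_key(df, genome))
    return CopyNumberProfile(df)


# ---------------------------------------------------------------------------
# replicates: dilution, perturbation, cohorts


def dilute_replicate(
    specimen: Specimen,
    dilution: float,
    seed: int,
    genome: GenomeModel | None = None,
    params: ScarParams | None = None,
    replicate_id: str = "R0",
    study: str = "LOD",
) -> ReplicateRecord:
    """Mix specimen DNA at mass fraction ``dilution`` with matched normal.

    Effective purity is ``dilution * specimen.purity`` (mass balance); VAFs
    are regenerated at the same SNP positions at the effective purity, and the
    observed profile is re-decoded from the correspondingly attenuated
    signals. QC assignment is left pending (``qc_valid=True``).
    """
    if not 0 < dilution <= 1:
        raise ValueError("dilution must lie in (0, 1]")
    if specimen.purity <= 0:
        raise ValueError("specimen purity must be > 0")
    params = params or ScarParams()
    rng = np.random.default_rng(seed)
    eff = dilution * specimen.purity
    vafs = sample_vafs(
        specimen.profile,
        specimen.vafs.rows["chrom"].values,
        specimen.vafs.rows["pos"].values,
        eff,
        params.depth,
        rng,
    )
    if genome is None:
        raise ValueError("genome required to decode the observed profile")
    obs = decode_observed_profile(specimen.profile, genome, eff, params.noise_sd, rng)
    return ReplicateRecord(
        replicate_id=replicate_id,
        specimen_id=specimen.specimen_id,
        study=study,
        dilution_level=dilution,
        effective_purity=eff,
        observed_profile=obs,
        observed_vafs=vafs,
    )


def apply_perturbations(
    replicate: ReplicateRecord,
    interferent: str | None,
    qc_fail_rates: tuple[float, float],
    seed: int,
    effects: dict | None = None,
) -> ReplicateRecord:
    """Assign QC validity and apply any interferent effect to a replicate.

    QC failure is two independent Bernoulli gates — library construction (LC)
    then hybrid capture (HC) — at the given rates. Interferent effects default
    to null for every configured substance; a configured ``depth_factor`` < 1
    deflates VAF depths and ``extra_noise_sd`` > 0 widens VAF noise.
    """
    effects = effects if effects is not None else DEFAULT_INTERFERENT_EFFECTS
    if interferent is not None and interferent not in effects:
        raise ValueError(f"unknown interferent {interferent!r}")
    rng = np.random.default_rng(seed)
    rep = dataclasses.replace(replicate)
    lc_rate, hc_rate = qc_fail_rates
    lc_fail = rng.random() < lc_rate
    hc_fail = rng.random() < hc_rate
    rep.qc_valid = not (lc_fail or hc_fail)
    rep.qc_fail_stage = "LC" if lc_fail else ("HC" if hc_fail else None)
    rep.interferent = interferent
    if interferent is not None and rep.observed_vafs is not None:
        eff = effects[interferent]
        if eff.get("depth_factor", 1.0) != 1.0 or eff.get("extra_noise_sd", 0.0) > 0:
            df = rep.observed_vafs.rows.copy()
            depth = np.maximum(
                (df["depth"].values * eff.get("depth_factor", 1.0)).astype(int), 1
            )
            vaf = df["vaf"].values + rng.normal(
                0, eff.get("extra_noise_sd", 0.0), len(df)
            )
            df["depth"] = depth
            df["vaf"] = np.clip(vaf, 0, 1)
            rep.observed_vafs = SnpVafTable(df)
    if not rep.qc_valid:
        rep.score = None
        rep.call = None
    return rep


# ---------------------------------------------------------------------------
# study cohort designs


#: Substance plan per sample archetype, mirroring the published interference
#: design: (interferent, concentration, n_replicates).
_INTERFERENCE_PLANS = {
    "bilirubin_panel": [
        ("conjugated_bilirubin", "0.8g/L", 2),
        ("dmso_control", None, 2),
        ("hemoglobin", "0.8g/L", 2),
        ("normal_control", None, 4),
        ("triglycerides", "148mmol/L", 2),
    ],
    "extraction_panel": [
        ("ethanol", "5%", 2),
        ("molecular_index_barcodes", "30%", 2),
        ("normal_control", None, 4),
        ("proteinase_k", "0.08mg/ml", 2),
    ],
    "melanin_panel": [
        ("ethanol", "5%", 2),
        ("melanin", "0.2ug/ml", 2),
        ("molecular_index_barcodes", "30%", 4),
        ("normal_control", None, 2),
        ("proteinase_k", "0.08mg/ml", 2),
    ],
    "unconjugated_panel": [
        ("dmso_control", None, 2),
        ("normal_control", None, 1),
        ("unconjugated_bilirubin", "0.2g/L", 2),
    ],
    "xylene_panel": [
        ("hemoglobin", "2mg/ml", 2),
        ("normal_control", None, 1),
        ("triglycerides", "37mmol/L", 2),
        ("xylene", "0.0001%", 2),
    ],
    "melanin_small_panel": [
        ("ethanol", "5%", 2),
        ("melanin", "0.2ug/ml", 2),
        ("normal_control", None, 2),
        ("proteinase_k", "0.08mg/ml", 2),
    ],
}

DEFAULT_DESIGNS: dict[str, dict] = {
    "LOB": {"n_specimens": 5, "replicates_per_specimen": 12, "qc_fail_rates": (0.0, 0.0)},
    "LOD": {
        "n_specimens": 3,
        "dilution_levels": (0.2, 0.25, 0.3, 0.35, 0.4),  # target purities
        "replicates_per_level": (19, 19, 19, 19, 18),
        "purity_range": (0.55, 0.75),
        "qc_fail_rates": (0.0, 0.053),
    },
    "PRECISION": {
        "n_positive": 11,
        "n_negative": 11,
        "n_sites": 3,
        "qc_fail_rates": (0.005, 0.010),
        "purity_range": (0.15, 0.85),
    },
    "CONCORDANCE": {
        "n_lof_rev": 101,
        "n_hrr_wildtype": 130,
        "purity_range": (0.08, 0.90),
        "qc_fail_rates": (0.0, 0.009),
    },
    "INTERFERENCE": {
        "substance_samples": [
            ("bilirubin_panel", "positive"),
            ("bilirubin_panel", "negative"),
            ("bilirubin_panel", "negative"),
            ("extraction_panel", "positive"),
            ("melanin_panel", "negative"),
            ("unconjugated_panel", "positive"),
            ("extraction_panel", "negative"),
            ("xylene_panel", "positive"),
            ("melanin_small_panel", "negative"),
            ("melanin_panel", "positive"),
            ("melanin_panel", "negative"),
        ],
        "necrosis_levels": ("5%", "10%", "15%", "25%", "40%", "50%"),
        "purity_range": (0.35, 0.85),
        "qc_fail_rates": (0.0, 0.0),
    },
}


def _spawn_seed(rng) -> int:
    return int(rng.integers(0, 2**31 - 1))


def _make_replicate(
    specimen, genome, params, rid, study, eff_purity, rng, **factors
) -> ReplicateRecord:
    obs = decode_observed_profile(
        specimen.profile, genome, eff_purity, params.noise_sd, rng
    )
    vafs = sample_vafs(
        specimen.profile,
        specimen.vafs.rows["chrom"].values,
        specimen.vafs.rows["pos"].values,
        eff_purity,
        params.depth,
        rng,
    )
    return ReplicateRecord(
        replicate_id=rid,
        specimen_id=specimen.specimen_id,
        study=study,
        effective_purity=eff_purity,
        observed_profile=obs,
        observed_vafs=vafs,
        **factors,
    )


def generate_study_cohort(
    design: dict,
    seed: int,
    genome: GenomeModel | None = None,
    params: ScarParams | None = None,
) -> tuple[dict[str, Specimen], list[ReplicateRecord]]:
    """Generate the specimens and replicate manifest for one study design.

    ``design`` must name a ``study`` in {LOB, LOD, PRECISION, CONCORDANCE,
    INTERFERENCE}; remaining keys override the study's defaults. Default
    shapes follow the published designs: LoB 5×12=60, LoD 3×5 levels ≈ 282,
    precision 22×36=792 (Table-1 factorial), concordance 101+130,
    interference per-substance plans.
    """
    from .genome import build_genome

    study = design.get("study", "").upper()
    if study not in STUDY_TYPES:
        raise ValueError(f"unknown study type {design.get('study')!r}")
    genome = genome or build_genome()
    params = params or ScarParams()
    cfg = dict(DEFAULT_DESIGNS[study])
    cfg.update({k: v for k, v in design.items() if k != "study"})
    rng = np.random.default_rng(seed)
    specimens: dict[str, Specimen] = {}
    reps: list[ReplicateRecord] = []

    if study == "LOB":
        for i in range(int(cfg["n_specimens"])):
            sp = simulate_specimen(
                genome, "blank", params, 1.0, _spawn_seed(rng),
                specimen_id=f"LOB{i + 1}", disease_label="normal",
                biomarker_truth="HRR_wildtype",
            )
            specimens[sp.specimen_id] = sp
            for j in range(int(cfg["replicates_per_specimen"])):
                rep = _make_replicate(
                    sp, genome, params, f"{sp.specimen_id}-r{j + 1}", study,
                    sp.purity, np.random.default_rng(_spawn_seed(rng)), plate=j + 1,
                )
                reps.append(
                    apply_perturbations(rep, None, cfg["qc_fail_rates"], _spawn_seed(rng))
                )

    elif study == "LOD":
        levels = tuple(cfg["dilution_levels"])
        per_level = tuple(cfg["replicates_per_level"])
        lo, hi = cfg["purity_range"]
        for i in range(int(cfg["n_specimens"])):
            purity = float(rng.uniform(lo, hi))
            sp = simulate_specimen(
                genome, "positive", params, purity, _spawn_seed(rng),
                specimen_id=f"LOD{i + 1}", disease_label="breast",
            )
            specimens[sp.specimen_id] = sp
            for level, n in zip(levels, per_level):
                d = min(level / purity, 1.0)
                for j in range(int(n)):
                    rep = dilute_replicate(
                        sp, d, _spawn_seed(rng), genome=genome, params=params,
                        replicate_id=f"{sp.specimen_id}-L{level}-r{j + 1}",
                    )
                    rep.dilution_level = level
                    rep.plate = j + 1
                    reps.append(
                        apply_perturbations(
                            rep, None, cfg["qc_fail_rates"], _spawn_seed(rng)
                        )
                    )

    elif study == "PRECISION":
        if int(cfg["n_sites"]) != 3:
            raise ValueError("precision design requires exactly 3 sites (36 replicates per specimen)")
        n_pos, n_neg = int(cfg["n_positive"]), int(cfg["n_negative"])
        lo, hi = cfg["purity_range"]
        labels = ["positive"] * n_pos + ["negative"] * n_neg
        for i, lab in enumerate(labels):
            purity = float(rng.uniform(lo, hi))
            sp = simulate_specimen(
                genome, lab, params, purity, _spawn_seed(rng),
                specimen_id=f"PRC{i + 1}",
                disease_label=["ovary", "breast", "prostate", "lung", "skin", "colon"][i % 6],
            )
            specimens[sp.specimen_id] = sp
            # Table-1 factorial: group 1 -> 3 lots x 2 sequencers; group 2 ->
            # 2 lots x 3 sequencing runs. Either way 6 run-cells per site,
            # 2 replicates per cell, 3 sites: 36 replicates per specimen.
            group1 = i % 2 == 0
            cells = (
                [(lot, seqr) for lot in (1, 2, 3) for seqr in (1, 2)]
                if group1
                else [(lot, run) for lot in (1, 2) for run in (1, 2, 3)]
            )
            plate = 0
            for site in range(1, 4):
                for lot, seqr in cells:
                    plate += 1
                    for k in (1, 2):
                        rep = _make_replicate(
                            sp, genome, params,
                            f"{sp.specimen_id}-s{site}-l{lot}-q{seqr}-k{k}",
                            study, sp.purity,
                            np.random.default_rng(_spawn_seed(rng)),
                            site=site, reagent_lot=lot, sequencer_or_run=seqr,
                            plate=plate, rep_k=k,
                        )
                        reps.append(
                            apply_perturbations(
                                rep, None, cfg["qc_fail_rates"], _spawn_seed(rng)
                            )
                        )

    elif study == "CONCORDANCE":
        lo, hi = cfg["purity_range"]
        plan = [("LOF_REV", "positive", int(cfg["n_lof_rev"]))] + [
            ("HRR_wildtype", "negative", int(cfg["n_hrr_wildtype"]))
        ]
        idx = 0
        for biomarker, lab, n in plan:
            for _ in range(n):
                idx += 1
                purity = float(rng.uniform(lo, hi))
                sp = simulate_specimen(
                    genome, lab, params, purity, _spawn_seed(rng),
                    specimen_id=f"CON{idx}", biomarker_truth=biomarker,
                    disease_label=["breast", "ovary", "pancreas", "prostate", "lung"][idx % 5],
                )
                specimens[sp.specimen_id] = sp
                rep = _make_replicate(
                    sp, genome, params, f"{sp.specimen_id}-r1", study, sp.purity,
                    np.random.default_rng(_spawn_seed(rng)),
                )
                reps.append(
                    apply_perturbations(rep, None, cfg["qc_fail_rates"], _spawn_seed(rng))
                )

    elif study == "INTERFERENCE":
        lo, hi = cfg["purity_range"]
        sid = 0
        for panel, lab in cfg["substance_samples"]:
            sid += 1
            purity = float(rng.uniform(lo, hi))
            sp = simulate_specimen(
                genome, lab, params, purity, _spawn_seed(rng),
                specimen_id=f"INT{sid}",
            )
            specimens[sp.specimen_id] = sp
            for substance, conc, n in _INTERFERENCE_PLANS[panel]:
                for j in range(n):
                    rep = _make_replicate(
                        sp, genome, params,
                        f"{sp.specimen_id}-{substance}-r{j + 1}", study,
                        sp.purity, np.random.default_rng(_spawn_seed(rng)),
                        plate=j + 1,
                    )
                    rep = apply_perturbations(
                        rep, substance, cfg["qc_fail_rates"], _spawn_seed(rng)
                    )
                    rep.interferent_concentration = conc
                    reps.append(rep)
        for level in cfg["necrosis_levels"]:
            sid += 1
            lab = "positive" if sid % 2 == 0 else "negative"
            purity = float(rng.uniform(lo, hi))
            sp = simulate_specimen(
                genome, lab, params, purity, _spawn_seed(rng),
                specimen_id=f"INT{sid}",
            )
            specimens[sp.specimen_id] = sp
            for j in range(2):
                rep = _make_replicate(
                    sp, genome, params, f"{sp.specimen_id}-necrotic-r{j + 1}",
                    study, sp.purity, np.random.default_rng(_spawn_seed(rng)),
                    plate=j + 1,
                )
                rep = apply_perturbations(
                    rep, "necrotic", cfg["qc_fail_rates"], _spawn_seed(rng)
                )
                rep.interferent_concentration = level
                reps.append(rep)

    return specimens, reps
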