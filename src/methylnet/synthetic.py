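"""Synthetic cohort generators.

Two cohorts are emulated: a small discovery cohort (6 Graves' orbitopathy
cases vs 6 controls, ~841 differentially methylated sites from reduced
representation bisulfite sequencing) whose methylation-fraction matrix feeds
the network pipeline, and an enlarged validation cohort (48 cases vs 24
controls) with per-locus percent-methylation levels measured by targeted
bisulfite sequencing.  A clinical phenotype table (age, sex, blood pressure,
BMI, disease duration, clinical activity score, TRAb titre) accompanies each.

Background methylation per site is drawn from a Beta distribution and
case-specific effects are injected additively on the logit scale, which keeps
every value inside [0, 1] while producing controllable fold changes between
group means.  One integer seed drives everything; per-stage sub-streams are
derived deterministically with :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

__all__ = [
    "CohortSpec",
    "LocusSpec",
    "ValidationCohortSpec",
    "MethylationMatrix",
    "DEFAULT_VALIDATION_LOCI",
    "TRAB_DETECTION_LIMIT",
    "simulate_discovery_cohort",
    "simulate_phenotypes",
    "simulate_validation_cohort",
]

#: TRAb assay lower detection limit in U/L; controls are below it and their
#: titre is recorded as missing in the phenotype table.
TRAB_DETECTION_LIMIT = 1.75

# Gene symbols seeded into the affected tails so that downstream candidate
# lists carry recognizable hub names; the remainder are synthetic labels.
_HYPO_SYMBOLS = ("BOLL", "HIST1H2AL", "EFCAB1", "FZD7", "CD14")
_HYPER_SYMBOLS = ("MBP", "ANGEL1", "LYAR", "BECN1", "CDK5", "DRD4", "IL17RE")


class InvalidSpecError(ValueError):
    """A cohort specification violates its invariants."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the discovery cohort generator.

    Attributes
    ----------
    n_sites : int
        Number of differentially methylated sites (default 841).
    n_case, n_ctrl : int
        Samples per group (default 6 vs 6).
    base_beta_alpha, base_beta_beta : float
        Shape parameters of the Beta background distribution of per-site
        methylation fractions.
    frac_hypo, frac_hyper : float
        Fractions of sites receiving a negative / positive logit-scale
        case effect (default 0.05 each, the percentile-tail mass).
    effect_log_fold : float
        Mean magnitude of the injected logit-scale effect (|log fold|-like).
    noise_sd : float
        Per-sample logit-scale Gaussian noise standard deviation.
    missing_rate : float
        Optional fraction of per-sample values set to missing; the default
        cohort is complete.
    seed : int
        Master seed for all randomness.
    """

    n_sites: int = 841
    n_case: int = 6
    n_ctrl: int = 6
    base_beta_alpha: float = 2.0
    base_beta_beta: float = 2.0
    frac_hypo: float = 0.05
    frac_hyper: float = 0.05
    effect_log_fold: float = 1.5
    noise_sd: float = 0.3
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites <= 0 or self.n_case <= 0 or self.n_ctrl <= 0:
            raise InvalidSpecError("n_sites, n_case and n_ctrl must be positive")
        if self.base_beta_alpha <= 0 or self.base_beta_beta <= 0:
            raise InvalidSpecError("Beta shape parameters must be positive")
        if not (0 <= self.frac_hypo <= 1 and 0 <= self.frac_hyper <= 1):
            raise InvalidSpecError("tail fractions must lie in [0, 1]")
        if self.frac_hypo + self.frac_hyper > 1:
            raise InvalidSpecError("frac_hypo + frac_hyper must not exceed 1")
        if self.effect_log_fold < 0:
            raise InvalidSpecError("effect_log_fold must be non-negative")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise InvalidSpecError("missing_rate must lie in [0, 1)")


@dataclass(frozen=True)
class LocusSpec:
    """One targeted validation locus: name, effect direction and group moments
    on the percent-methylation scale."""

    name: str
    direction: str  # "hypo" | "hyper" | "null"
    mean_case: float
    mean_ctrl: float
    sd_case: float
    sd_ctrl: float
    chrom: str = "NA"
    position: int = 0

    def __post_init__(self) -> None:
        if self.direction not in ("hypo", "hyper", "null"):
            raise InvalidSpecError(f"unknown direction {self.direction!r}")
        for m in (self.mean_case, self.mean_ctrl):
            if not 0 <= m <= 100:
                raise InvalidSpecError("locus means must lie in [0, 100]")
        if self.sd_case < 0 or self.sd_ctrl < 0:
            raise InvalidSpecError("locus standard deviations must be non-negative")


# Default 9-locus panel.  The hypo-methylated locus carries the design-point
# effect (mean difference 12.86, SDs 3.30 / 10.76) used for the cohort's
# power calculation; two hyper loci carry effects of similar standardized
# size; four loci carry moderate effects and two are null.
DEFAULT_VALIDATION_LOCI: tuple[LocusSpec, ...] = (
    LocusSpec("BOLL", "hypo", 52.14, 65.0, 3.30, 10.76, "2", 198651436),
    LocusSpec("CDK5", "hyper", 52.0, 40.0, 9.0, 7.0, "7", 150754945),
    LocusSpec("MBP", "hyper", 66.0, 55.0, 9.5, 8.0, "18", 74844255),
    LocusSpec("ANGEL1", "hyper", 58.0, 52.0, 9.0, 9.0, "14", 77258970),
    LocusSpec("BECN1", "hyper", 47.5, 42.0, 8.5, 8.5, "17", 40962149),
    LocusSpec("LYAR", "hyper", 61.0, 55.0, 9.0, 9.0, "4", 4269685),
    LocusSpec("IL17RE", "hyper", 44.0, 39.0, 8.0, 8.0, "3", 9959632),
    LocusSpec("CD14", "null", 50.0, 50.0, 9.0, 9.0, "5", 140011313),
    LocusSpec("DRD4", "null", 45.0, 45.0, 9.0, 9.0, "11", 637269),
)


@dataclass(frozen=True)
class ValidationCohortSpec:
    """Parameters of the enlarged validation cohort generator."""

    n_case: int = 48
    n_ctrl: int = 24
    loci: tuple[LocusSpec, ...] = DEFAULT_VALIDATION_LOCI
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case <= 0 or self.n_ctrl <= 0:
            raise InvalidSpecError("n_case and n_ctrl must be positive")
        if not self.loci:
            raise InvalidSpecError("at least one locus is required")


@dataclass
class MethylationMatrix:
    """Sites-by-samples methylation fractions with group labels.

    ``values`` is indexed by node id (``gene@chrom:start``) with one column
    per sample; ``groups`` maps each sample id to ``"case"`` or ``"ctrl"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    @property
    def case_columns(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == "case"]

    @property
    def ctrl_columns(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == "ctrl"]

    def restrict(self, node_ids: Sequence[str]) -> "MethylationMatrix":
        return MethylationMatrix(self.values.loc[list(node_ids)], self.groups)


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_discovery_cohort(spec: CohortSpec) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Simulate the discovery cohort and its DMR table.

    Returns the methylation matrix and a DMR table with one row per site:
    node_id, chrom, start, end, gene, status (hypo/hyper/null truth label),
    mean_case, mean_ctrl, fold_change (= mean_case / mean_ctrl) and a Welch
    t-test P value on the per-sample fractions.  Exactly
    ``round(frac_hypo * n_sites)`` sites carry a negative logit effect and
    ``round(frac_hyper * n_sites)`` a positive one.
    """
    rng_base, rng_eff, rng_noise, rng_pos, rng_miss = _rngs(spec.seed, 5)
    n = spec.n_sites
    n_samples = spec.n_case + spec.n_ctrl

    base = rng_base.beta(spec.base_beta_alpha, spec.base_beta_beta, size=n)
    base = np.clip(base, 0.02, 0.98)  # keep logit finite

    n_hypo = int(round(spec.frac_hypo * n))
    n_hyper = int(round(spec.frac_hyper * n))
    status = np.array(["null"] * n, dtype=object)
    order = rng_eff.permutation(n)
    hypo_idx = order[:n_hypo]
    hyper_idx = order[n_hypo:n_hypo + n_hyper]
    status[hypo_idx] = "hypo"
    status[hyper_idx] = "hyper"

    shift = np.zeros(n)
    if spec.effect_log_fold > 0:
        # Gamma(4, eff/4): mean effect_log_fold, little mass near zero, so
        # affected sites reliably populate the fold-change tails.
        mag = rng_eff.gamma(4.0, spec.effect_log_fold / 4.0, size=n)
        shift[hypo_idx] = -mag[hypo_idx]
        shift[hyper_idx] = mag[hyper_idx]

    base_logit = logit(base)[:, None]
    group_shift = np.where(np.arange(n_samples) < spec.n_case, shift[:, None], 0.0)
    noise = rng_noise.normal(0.0, spec.noise_sd, size=(n, n_samples)) if spec.noise_sd > 0 else 0.0
    vals = expit(base_logit + group_shift + noise)

    if spec.missing_rate > 0:
        mask = rng_miss.random(size=(n, n_samples)) < spec.missing_rate
        vals = np.where(mask, np.nan, vals)

    sample_ids = [f"case_{i + 1}" for i in range(spec.n_case)] + [
        f"ctrl_{i + 1}" for i in range(spec.n_ctrl)
    ]
    groups = pd.Series(
        ["case"] * spec.n_case + ["ctrl"] * spec.n_ctrl, index=sample_ids, name="group"
    )

    genes = np.array([f"GENE{i:04d}" for i in range(n)], dtype=object)
    for sym, idx in zip(_HYPO_SYMBOLS, hypo_idx):
        genes[idx] = sym
    for sym, idx in zip(_HYPER_SYMBOLS, hyper_idx):
        genes[idx] = sym

    chroms = rng_pos.integers(1, 23, size=n).astype(str)
    starts = rng_pos.integers(10_000, 100_000_000, size=n)
    ends = starts + rng_pos.integers(50, 500, size=n)
    node_ids = np.array(
        [f"{g}@{c}:{s}" for g, c, s in zip(genes, chroms, starts)], dtype=object
    )

    case_vals = vals[:, : spec.n_case]
    ctrl_vals = vals[:, spec.n_case:]
    mean_case = np.nanmean(case_vals, axis=1)
    mean_ctrl = np.nanmean(ctrl_vals, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = mean_case / mean_ctrl

    with np.errstate(divide="ignore", invalid="ignore"):
        _, pvals = stats.ttest_ind(
            case_vals, ctrl_vals, axis=1, equal_var=False, nan_policy="omit"
        )
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)  # zero-variance null sites

    matrix = MethylationMatrix(
        pd.DataFrame(vals, index=pd.Index(node_ids, name="node_id"), columns=sample_ids),
        groups,
    )
    dmrs = pd.DataFrame(
        {
            "node_id": node_ids,
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "gene": genes,
            "status": status,
            "mean_case": mean_case,
            "mean_ctrl": mean_ctrl,
            "fold_change": fold,
            "p_value": pvals,
        }
    )
    return matrix, dmrs


def simulate_phenotypes(n_case: int, n_ctrl: int, seed: int = 0) -> pd.DataFrame:
    """Simulate a clinical phenotype table.

    Per-group moments target the validation cohort's baseline table: cases
    aged 46.0 +/- 11.4 vs controls 43.4 +/- 5.5 years, male fractions 23/48
    and 11/24, blood pressure and anthropometrics with the published group
    means and SDs.  Disease duration, clinical activity score (CAS) and TRAb
    titre exist for cases only; controls' TRAb sits below the 1.75 U/L
    detection limit and is recorded as missing.  TRAb is log-normal, matching
    the published median 4.50 (IQR 1.69-9.64).
    """
    if n_case <= 0 or n_ctrl <= 0:
        raise InvalidSpecError("n_case and n_ctrl must be positive")
    (rng,) = _rngs(seed, 1)

    def group(n: int, is_case: bool) -> pd.DataFrame:
        if is_case:
            age = rng.normal(46.0, 11.4, n)
            male = rng.random(n) < 23 / 48
            height = rng.normal(165.9, 8.1, n)
            weight = rng.normal(68.5, 14.4, n)
            sbp = rng.normal(121.9, 9.6, n)
            dbp = rng.normal(74.0, 6.1, n)
            duration = rng.gamma(2.0, 9.7 / 2.0, n)  # mean 9.7 months, skewed
            cas = np.clip(np.rint(rng.normal(3.0, 0.8, n)), 0, None).astype(float)
            # log-median ln 4.50, sigma from IQR (ln 9.64 - ln 1.69)/(2*0.6745)
            trab = rng.lognormal(np.log(4.50), 1.2905, n)
        else:
            age = rng.normal(43.4, 5.5, n)
            male = rng.random(n) < 11 / 24
            height = rng.normal(166.9, 6.5, n)
            weight = rng.normal(66.0, 12.9, n)
            sbp = rng.normal(121.0, 18.1, n)
            dbp = rng.normal(73.0, 18.5, n)
            duration = np.full(n, np.nan)
            cas = np.full(n, np.nan)
            trab = np.full(n, np.nan)
        height = np.clip(height, 140.0, 200.0)
        weight = np.clip(weight, 35.0, 150.0)
        return pd.DataFrame(
            {
                "group": "case" if is_case else "ctrl",
                "age": np.clip(age, 18.0, None),
                "sex": np.where(male, "M", "F"),
                "height": height,
                "weight": weight,
                "SBP": sbp,
                "DBP": dbp,
                "BMI": weight / (height / 100.0) ** 2,
                "duration": duration,
                "CAS": cas,
                "TRAb": trab,
            }
        )

    out = pd.concat([group(n_case, True), group(n_ctrl, False)], ignore_index=True)
    out.insert(
        0,
        "sample_id",
        [f"case_{i + 1}" for i in range(n_case)] + [f"ctrl_{i + 1}" for i in range(n_ctrl)],
    )
    return out.set_index("sample_id")


def simulate_validation_cohort(spec: ValidationCohortSpec) -> pd.DataFrame:
    """Simulate per-locus percent-methylation levels for the enlarged cohort.

    Values are drawn from group-specific normals truncated to [0, 100]; a
    zero SD yields the group mean exactly.  Returns a samples-by-loci table
    with a leading ``group`` column.
    """
    (rng,) = _rngs(spec.seed, 1)
    n = spec.n_case + spec.n_ctrl
    sample_ids = [f"case_{i + 1}" for i in range(spec.n_case)] + [
        f"ctrl_{i + 1}" for i in range(spec.n_ctrl)
    ]
    data: dict[str, np.ndarray] = {}
    for locus in spec.loci:
        col = np.empty(n)
        for sl, mean, sd in (
            (slice(0, spec.n_case), locus.mean_case, locus.sd_case),
            (slice(spec.n_case, n), locus.mean_ctrl, locus.sd_ctrl),
        ):
            m = sl.stop - sl.start
            if sd == 0:
                col[sl] = mean
            else:
                a, b = (0.0 - mean) / sd, (100.0 - mean) / sd
                col[sl] = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=m, random_state=rng)
        data[locus.name] = col
    out = pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id"))
    out.insert(0, "group", ["case"] * spec.n_case + ["ctrl"] * spec.n_ctrl)
    return out
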