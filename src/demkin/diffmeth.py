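"""Paired differential methylation and expression testing.

The workhorse is a one-sample moderated t-test on per-patient paired
differences (later minus earlier timepoint of the same patient), with
empirical-Bayes variance shrinkage: per-feature sample variances s_g^2
with d = n - 1 degrees of freedom are assumed to follow a scaled
F/inverse-chi-square hierarchy with prior (d0, s0^2); the posterior
variance is

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

and t~_g = mean_diff_g / (s~_g / sqrt(n)) is referred to a t distribution
on d + d0 degrees of freedom.  The hyperparameters are estimated by
method-of-moments on the log sample variances (digamma/trigamma moment
matching).  With d0 forced to 0 the statistic reduces exactly to the
ordinary one-sample t.

Serial designs justify the paired formulation: each patient's later
sample is contrasted with their own matched day-0 sample, removing the
large inter-patient baseline differences from the error term.  An
unpaired two-group moderated t is available for sensitivity analysis.

Effect sizes and calls live on the beta scale: a CpG is called
demethylated when its BH-adjusted p-value is below alpha *and* its mean
beta difference is below -delta_threshold (strict inequalities).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datamodel import (
    DEFAULT_EPSILON,
    BetaMatrix,
    PairedDesign,
    SampleSheet,
    beta_to_m,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# empirical-Bayes variance prior
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariancePrior:
    """Prior degrees of freedom and prior variance for shrinkage."""

    d0: float
    s2_0: float


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    trigamma is strictly decreasing and convex on (0, inf), so the
    iteration on 1/trigamma converges monotonically from the starting
    value x = 0.5 + 1/y.
    """
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < tol:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> VariancePrior:
    """Method-of-moments fit of (d0, s0^2) from sample variances.

    Uses the log-variance moments: for s^2 ~ s0^2 * F(d, d0) (scaled),
    e = log(s^2) - digamma(d/2) + log(d/2) has mean
    log(s0^2) + digamma(d0/2) - log(d0/2) and variance
    trigamma(d/2) + trigamma(d0/2).  Zero variances are excluded from
    the fit (they carry no information about the scale); if the excess
    log-variance dispersion is non-positive the prior degrees of freedom
    go to infinity (fully pooled variance) with a logged warning.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size == 0:
        raise ValueError("all feature variances are zero; no variance to pool")
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(np.mean(e))
    if pos.size < 2:
        logger.warning("single usable variance; prior df set to infinity")
        return VariancePrior(d0=math.inf, s2_0=float(math.exp(emean)))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s2_0 = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        logger.warning(
            "log-variance dispersion at or below sampling noise; "
            "prior df set to infinity (fully pooled variance)"
        )
        d0, s2_0 = math.inf, math.exp(emean)
    return VariancePrior(d0=float(d0), s2_0=float(s2_0))


def moderated_paired_test(
    values: pd.DataFrame | object,
    design: PairedDesign,
    prior_override: VariancePrior | tuple | None = None,
) -> pd.DataFrame:
    """One-sample moderated t on per-patient paired differences.

    Parameters
    ----------
    values : feature x sample frame (or a matrix container with ``.data``)
        on the scale to be tested (m-values or log2 intensities).
    design : the per-patient (t1, t0) column pairing; n >= 2 required.
    prior_override : optional (d0, s2_0); d0 = 0 yields the ordinary
        paired t exactly, d0 = inf fully pools the variance.

    Returns
    -------
    DataFrame indexed by feature with columns ``mean_diff``, ``mod_t``,
    ``p`` (two-sided), plus the fitted prior in ``.attrs``.
    """
    data = getattr(values, "data", values)
    if design.n < 2:
        raise ValueError(f"paired test requires >= 2 patients, got {design.n}")
    diffs = data[list(design.t1_samples)].to_numpy() - data[list(design.t0_samples)].to_numpy()
    n = design.n
    d = n - 1
    mean_diff = diffs.mean(axis=1)
    s2 = diffs.var(axis=1, ddof=1)

    if prior_override is not None:
        if not isinstance(prior_override, VariancePrior):
            prior_override = VariancePrior(*prior_override)
        prior = prior_override
    else:
        prior = estimate_variance_prior(s2, d)

    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s2_0)
        df_total = math.inf
    else:
        s2_post = (prior.d0 * prior.s2_0 + d * s2) / (prior.d0 + d)
        df_total = d + prior.d0

    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_diff / np.sqrt(s2_post / n)
    # degenerate features: zero posterior variance
    zero = s2_post == 0
    t[zero & (mean_diff == 0)] = 0.0
    t[zero & (mean_diff > 0)] = np.inf
    t[zero & (mean_diff < 0)] = -np.inf
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    out = pd.DataFrame({"mean_diff": mean_diff, "mod_t": t, "p": p}, index=data.index)
    out.attrs["prior_d0"] = prior.d0
    out.attrs["prior_s2_0"] = prior.s2_0
    out.attrs["df_total"] = df_total
    out.attrs["n"] = n
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def group_delta_beta(beta: BetaMatrix, design: PairedDesign) -> pd.Series:
    """Mean over patients of per-patient beta differences (t1 - t0)."""
    diffs = beta.select_samples(design.t1_samples).to_numpy() - beta.select_samples(
        design.t0_samples
    ).to_numpy()
    return pd.Series(diffs.mean(axis=1), index=beta.data.index, name="delta_beta")


def call_demethylated(
    delta_beta: pd.Series,
    adj_p: pd.Series,
    alpha: float = 0.05,
    delta_threshold: float = 0.1,
    direction: str = "hypo",
) -> set[str]:
    """Significance call: adj_p < alpha and delta beta beyond the threshold.

    ``direction="hypo"`` selects delta beta < -delta_threshold
    (demethylation); ``"hyper"`` selects delta beta > +delta_threshold
    (remethylation).  Inequalities are strict.
    """
    if direction not in ("hypo", "hyper"):
        raise ValueError(f"direction must be 'hypo' or 'hyper', got {direction!r}")
    sig = adj_p < alpha
    if direction == "hypo":
        eff = delta_beta < -delta_threshold
    else:
        eff = delta_beta > delta_threshold
    return set(delta_beta.index[(sig & eff).to_numpy()])


# ---------------------------------------------------------------------------
# Model / Results front end
# ---------------------------------------------------------------------------


class PairedDifferentialModel:
    """Paired differential methylation model for one contrast.

    Transforms betas to m-values (clamped logit2), runs the moderated
    paired t across CpGs, attaches beta-scale effect sizes and BH-adjusted
    p-values, and exposes threshold-based call sets via the results object.
    """

    def __init__(
        self,
        beta: BetaMatrix,
        design: PairedDesign,
        epsilon: float = DEFAULT_EPSILON,
    ):
        self.beta = beta
        self.design = design
        self.epsilon = epsilon

    def fit(
        self,
        alpha: float = 0.05,
        delta_threshold: float = 0.1,
        prior_override=None,
    ) -> "DiffMethResults":
        mvals = beta_to_m(self.beta, self.epsilon)
        table = moderated_paired_test(mvals, self.design, prior_override=prior_override)
        attrs = dict(table.attrs)
        table = table.rename(columns={"mean_diff": "delta_m"})
        table.insert(0, "delta_beta", group_delta_beta(self.beta, self.design))
        table["adj_p"] = bh_adjust(table["p"].to_numpy())
        table["demethylated_call"] = (table["adj_p"] < alpha) & (
            table["delta_beta"] < -delta_threshold
        )
        table["remethylated_call"] = (table["adj_p"] < alpha) & (
            table["delta_beta"] > delta_threshold
        )
        return DiffMethResults(
            table=table,
            design=self.design,
            alpha=alpha,
            delta_threshold=delta_threshold,
            prior=VariancePrior(attrs["prior_d0"], attrs["prior_s2_0"]),
            df_total=attrs["df_total"],
        )


@dataclass
class DiffMethResults:
    """Per-CpG moderated-test results with beta-scale calls."""

    table: pd.DataFrame
    design: PairedDesign
    alpha: float
    delta_threshold: float
    prior: VariancePrior
    df_total: float

    def demethylated_set(self) -> set[str]:
        return set(self.table.index[self.table["demethylated_call"].to_numpy()])

    def remethylated_set(self) -> set[str]:
        return set(self.table.index[self.table["remethylated_call"].to_numpy()])

    def summary(self) -> str:
        t = self.table
        lines = [
            f"Paired differential methylation: {self.design.label()}",
            f"  patients: {self.design.n}   features: {len(t)}",
            f"  prior df: {self.prior.d0:.4g}   prior s2: {self.prior.s2_0:.4g}"
            f"   total df: {self.df_total:.4g}",
            f"  thresholds: adj_p < {self.alpha:g}, |delta beta| > {self.delta_threshold:g}",
            f"  demethylated calls: {int(t['demethylated_call'].sum())}",
            f"  remethylated calls: {int(t['remethylated_call'].sum())}",
            f"  median delta beta: {t['delta_beta'].median():.4f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# single-sample calls and cohort kinetics
# ---------------------------------------------------------------------------


def single_sample_delta_sets(
    beta: BetaMatrix,
    sheet: SampleSheet,
    t1: str,
    t0: str,
    cycle: int = 1,
    cell_type: str = "blast",
    delta_threshold: float = 0.1,
    direction: str = "hypo",
) -> tuple[dict[str, set[str]], list[str]]:
    """Per-patient CpG sets with raw delta beta beyond the threshold.

    A single pair yields no variance estimate, so the call is on the raw
    per-patient beta difference only.  Returns (patient -> CpG set,
    patients omitted for lack of a timepoint).
    """
    design = sheet.paired_design(t1, t0, cycle=cycle, cell_type=cell_type)
    omitted = sheet.unpaired_patients(t1, t0, cycle=cycle, cell_type=cell_type)
    if omitted:
        logger.info("single-sample %s vs %s: omitted patients without both timepoints: %s",
                    t1, t0, omitted)
    diffs = beta.select_samples(design.t1_samples).to_numpy() - beta.select_samples(
        design.t0_samples
    ).to_numpy()
    index = np.asarray(beta.cpg_ids, dtype=object)
    sets = {}
    for k, patient in enumerate(design.patients):
        if direction == "hypo":
            mask = diffs[:, k] < -delta_threshold
        else:
            mask = diffs[:, k] > delta_threshold
        sets[patient] = set(index[mask])
    return sets, omitted


def classify_demethylation_magnitude(
    count: int,
    strong_threshold: int = 100_000,
    limited_threshold: int = 25_000,
) -> str:
    """Bin a per-patient demethylated-CpG count into strong / intermediate /
    limited response categories (strict inequalities at both boundaries).

    Default boundaries refer to full 450K scale (~456k CpGs); pass scaled
    thresholds for reduced universes.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if count > strong_threshold:
        return "strong"
    if count < limited_threshold:
        return "limited"
    return "intermediate"


@dataclass
class CohortMethylationSummary:
    """Per-timepoint medians and baseline-stratified demethylation rates."""

    median_beta: dict[str, float]
    call_rate_by_baseline_bin: dict[str, float]
    n_pairs: int

    def summary(self) -> str:
        med = "  ".join(f"{tp}: {v:.3f}" for tp, v in self.median_beta.items())
        rates = "  ".join(f"{b}: {v:.4f}" for b, v in self.call_rate_by_baseline_bin.items())
        return (
            f"Cohort methylation summary ({self.n_pairs} patient pairs)\n"
            f"  median beta   {med}\n"
            f"  demethylation-call rate by baseline bin   {rates}"
        )


def cohort_methylation_summary(
    beta: BetaMatrix,
    sheet: SampleSheet,
    cell_type: str = "blast",
    cycle: int = 1,
    delta_threshold: float = 0.1,
) -> CohortMethylationSummary:
    """Median beta per timepoint plus demethylation-call rates stratified by
    each patient's baseline (day 0) methylation bin [0, 0.5] vs (0.5, 1].

    The call rate pools (CpG, patient) pairs: the fraction of pairs within
    a baseline bin whose day-8 single-sample delta beta is below
    -delta_threshold.
    """
    medians: dict[str, float] = {}
    for tp in ("d0", "d8", "d15"):
        sub = sheet.samples(timepoint=tp, cycle=cycle, cell_type=cell_type)
        if len(sub):
            medians[tp] = float(np.median(beta.select_samples(sub["sample_id"]).to_numpy()))
    design = sheet.paired_design("d8", "d0", cycle=cycle, cell_type=cell_type)
    b0 = beta.select_samples(design.t0_samples).to_numpy()
    b1 = beta.select_samples(design.t1_samples).to_numpy()
    called = (b1 - b0) < -delta_threshold
    low = b0 <= 0.5
    rates = {
        "[0,0.5]": float(called[low].mean()) if low.any() else float("nan"),
        "(0.5,1]": float(called[~low].mean()) if (~low).any() else float("nan"),
    }
    return CohortMethylationSummary(
        median_beta=medians, call_rate_by_baseline_bin=rates, n_pairs=design.n
    )
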