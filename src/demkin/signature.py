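"""Non-randomness testing of common demethylation.

The central question: is the set of CpGs demethylated in *all* patients
larger than expected if each patient had demethylated the same number of
CpGs at random positions?  The null preserves each patient's call burden:
per iteration, one uniform random CpG subset per patient, matched to that
patient's observed demethylated-set size, is drawn from the universe and
the across-patient intersection size recorded.  Because observed common
counts can sit hundreds of standard deviations above a 1000-iteration
null, the tail probability is computed parametrically from a normal fit
to the null counts rather than as an empirical rank.

Also here: cycle-1 vs cycle-2 concordance of call sets, per-sample Fisher
enrichment of a signature among single-sample calls, and the responder
80/20 screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _conditional_odds_ratio


def common_demethylated_set(
    per_patient_sets: Mapping[str, set],
    groupwise_significant: set | None = None,
    min_fraction: float = 1.0,
) -> set:
    """CpGs called in at least ``min_fraction`` of patients, intersected
    with the group-wise significant set (``min_fraction=1.0`` = all
    patients).  ``groupwise_significant=None`` skips the group filter.
    """
    if not per_patient_sets:
        raise ValueError("per_patient_sets is empty")
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must be in (0, 1]")
    n = len(per_patient_sets)
    counts: dict = {}
    for s in per_patient_sets.values():
        for cpg in s:
            counts[cpg] = counts.get(cpg, 0) + 1
    out = {cpg for cpg, c in counts.items() if c / n >= min_fraction}
    if groupwise_significant is not None:
        out &= set(groupwise_significant)
    return out


def random_set_null(
    per_patient_set_sizes: Mapping[str, int],
    universe,
    n_iterations: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Null distribution of the across-patient intersection size.

    Per iteration and patient, a uniform random subset (without
    replacement) of the patient's observed size is drawn from the
    universe; the size of the intersection over patients is recorded.
    """
    sizes = [int(s) for s in per_patient_set_sizes.values()]
    n_universe = len(universe)
    if any(s < 0 for s in sizes):
        raise ValueError("set sizes must be >= 0")
    if any(s > n_universe for s in sizes):
        raise ValueError("a set size exceeds the universe size")
    if not sizes:
        raise ValueError("no patients")
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = np.empty(n_iterations, dtype=np.int64)
    for it in range(n_iterations):
        mask = np.ones(n_universe, dtype=bool)
        for size in sizes:
            chosen = rng.choice(n_universe, size=size, replace=False)
            m = np.zeros(n_universe, dtype=bool)
            m[chosen] = True
            mask &= m
        counts[it] = int(mask.sum())
    return counts


def normal_tail_p(observed: float, null_counts) -> float:
    """Upper-tail normal p: 1 - Phi((observed - mean) / sd) on the null.

    With a degenerate null (sd = 0) the p-value is 0 if the observation
    exceeds the null mean and 1 otherwise; callers that need to know use
    :func:`null_is_degenerate`.
    """
    null_counts = np.asarray(null_counts, dtype=float)
    if null_counts.size == 0:
        raise ValueError("empty null vector")
    mean = null_counts.mean()
    sd = null_counts.std(ddof=1) if null_counts.size > 1 else 0.0
    if sd == 0.0:
        return 0.0 if observed > mean else 1.0
    return float(stats.norm.sf((observed - mean) / sd))


def null_is_degenerate(null_counts) -> bool:
    null_counts = np.asarray(null_counts, dtype=float)
    return null_counts.size < 2 or float(null_counts.std(ddof=1)) == 0.0


@dataclass
class SignatureNullResult:
    """Observed common-demethylation count against the resampling null."""

    observed_common_count: int
    null_counts: np.ndarray
    null_mean: float
    null_sd: float
    p_tail: float
    signature_cpg_ids: set
    n_iterations: int
    seed: int | None
    degenerate: bool

    @property
    def z(self) -> float:
        if self.null_sd == 0.0:
            return float("inf") if self.observed_common_count > self.null_mean else float("nan")
        return (self.observed_common_count - self.null_mean) / self.null_sd

    def summary(self) -> str:
        lines = [
            "Random-CpG-set resampling null for common demethylation",
            f"  iterations: {self.n_iterations}   seed: {self.seed}",
            f"  observed common CpGs: {self.observed_common_count}",
            f"  null mean: {self.null_mean:.3f}   null sd: {self.null_sd:.3f}",
            f"  upper-tail normal p: {self.p_tail:.4g}"
            + ("   [degenerate null]" if self.degenerate else f"   (z = {self.z:.2f})"),
        ]
        return "\n".join(lines)


class SignatureNullModel:
    """Common-demethylation signature test for a patient -> CpG-set map.

    ``fit`` intersects the per-patient sets (optionally filtered by the
    group-wise significant set), resamples size-matched random sets per
    patient, and returns the parametric upper-tail p.
    """

    def __init__(
        self,
        per_patient_sets: Mapping[str, set],
        universe,
        groupwise_significant: set | None = None,
        min_fraction: float = 1.0,
    ):
        if not per_patient_sets:
            raise ValueError("per_patient_sets is empty")
        universe = list(universe)
        uni = set(universe)
        for patient, s in per_patient_sets.items():
            extra = set(s) - uni
            if extra:
                raise ValueError(
                    f"patient {patient!r} has CpGs outside the universe: "
                    f"{sorted(extra)[:3]}..."
                )
        self.per_patient_sets = dict(per_patient_sets)
        self.universe = universe
        self.groupwise_significant = groupwise_significant
        self.min_fraction = min_fraction

    def fit(self, n_iterations: int = 1000, seed: int | None = None) -> SignatureNullResult:
        signature = common_demethylated_set(
            self.per_patient_sets, self.groupwise_significant, self.min_fraction
        )
        sizes = {p: len(s) for p, s in self.per_patient_sets.items()}
        null = random_set_null(sizes, self.universe, n_iterations=n_iterations, seed=seed)
        p = normal_tail_p(len(signature), null)
        return SignatureNullResult(
            observed_common_count=len(signature),
            null_counts=null,
            null_mean=float(null.mean()),
            null_sd=float(null.std(ddof=1)) if null.size > 1 else 0.0,
            p_tail=p,
            signature_cpg_ids=signature,
            n_iterations=n_iterations,
            seed=seed,
            degenerate=null_is_degenerate(null),
        )


# ---------------------------------------------------------------------------
# cycle concordance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CycleOverlap:
    """Exact overlap between two call sets (e.g. cycle 1 vs cycle 2)."""

    intersection: frozenset
    n_first: int
    n_second: int
    n_common: int
    fraction_recurring: float  # |A & B| / |A|


def cycle_overlap(set_cycle1: set, set_cycle2: set) -> CycleOverlap:
    a, b = set(set_cycle1), set(set_cycle2)
    inter = a & b
    frac = len(inter) / len(a) if a else float("nan")
    return CycleOverlap(
        intersection=frozenset(inter),
        n_first=len(a),
        n_second=len(b),
        n_common=len(inter),
        fraction_recurring=frac,
    )


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------


def fisher_exact_upper(table) -> tuple[float, float]:
    """One-sided (over-representation) Fisher exact test on a 2x2 table.

    Returns (conditional-MLE odds ratio, p = hypergeometric upper tail
    P(X >= x11) with margins fixed).
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    p = float(stats.fisher_exact(arr, alternative="greater")[1])
    orat = float(_conditional_odds_ratio(arr, kind="conditional").statistic)
    return orat, p


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 enrichment of a signature among one sample's call set."""

    n_signature_called: int
    n_signature_not_called: int
    n_called_not_signature: int
    n_neither: int
    odds_ratio: float
    p: float
    pct_universe_called: float
    pct_signature_called: float
    stars: str
    degenerate: bool = False

    @property
    def table(self) -> np.ndarray:
        return np.array(
            [
                [self.n_signature_called, self.n_signature_not_called],
                [self.n_called_not_signature, self.n_neither],
            ],
            dtype=np.int64,
        )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def signature_enrichment_per_sample(
    signature: set,
    per_patient_sets: Mapping[str, set],
    universe: set,
) -> dict[str, EnrichmentResult]:
    """Per patient, is the signature over-represented among that patient's
    demethylated CpGs?  Classifies every universe CpG by (in signature) x
    (called in this sample) and runs an upper-tail Fisher test.
    """
    universe = set(universe)
    signature = set(signature)
    if not signature <= universe:
        raise ValueError("signature is not a subset of the universe")
    out = {}
    for patient, called in per_patient_sets.items():
        called = set(called) & universe
        a = len(signature & called)
        b = len(signature) - a
        c = len(called) - a
        d = len(universe) - a - b - c
        degenerate = len(called) == 0
        if degenerate:
            orat, p = float("nan"), 1.0
        else:
            orat, p = fisher_exact_upper([[a, b], [c, d]])
        out[patient] = EnrichmentResult(
            n_signature_called=a,
            n_signature_not_called=b,
            n_called_not_signature=c,
            n_neither=d,
            odds_ratio=orat,
            p=p,
            pct_universe_called=100.0 * len(called) / len(universe) if universe else 0.0,
            pct_signature_called=100.0 * a / len(signature) if signature else 0.0,
            stars=_stars(p),
            degenerate=degenerate,
        )
    return out


# ---------------------------------------------------------------------------
# responder screen
# ---------------------------------------------------------------------------


def responder_screen(
    per_patient_sets: Mapping[str, set],
    groups: Mapping[str, str],
    hi: float = 0.8,
    lo: float = 0.2,
) -> set:
    """CpGs demethylated in >= ``hi`` of responders and <= ``lo`` of
    non-responders (inclusive bounds).

    ``groups`` maps patient -> 'responder' / 'nonresponder'; patients with
    any other label are ignored.  Both groups must be non-empty.
    """
    responders = [p for p, g in groups.items() if g == "responder" and p in per_patient_sets]
    nonresponders = [
        p for p, g in groups.items() if g == "nonresponder" and p in per_patient_sets
    ]
    if not responders or not nonresponders:
        raise ValueError("both responder and non-responder groups must be non-empty")
    candidates = set()
    for p in responders:
        candidates |= set(per_patient_sets[p])
    out = set()
    n_r, n_n = len(responders), len(nonresponders)
    for cpg in candidates:
        f_r = sum(cpg in per_patient_sets[p] for p in responders) / n_r
        if f_r < hi:
            continue
        f_n = sum(cpg in per_patient_sets[p] for p in nonresponders) / n_n
        if f_n <= lo:
            out.add(cpg)
    return out
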