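"""Core data containers for 450K-style methylation analysis.

The central object is a beta-value matrix (CpG x sample methylation
fractions in [0, 1]).  Statistical testing happens on the m-value scale
(logit2 of beta), which is approximately homoscedastic; effect sizes and
call thresholds stay on the beta scale, where a difference has a direct
interpretation as a change in the fraction of methylated alleles.

All containers are thin, validating wrappers around pandas objects: they
adopt (do not copy) the frame handed to them and fail loudly on malformed
input instead of imputing or coercing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Region categories counted as promoter when averaging beta values per gene.
PROMOTER_CATEGORIES = frozenset({"TSS1500", "TSS200", "5UTR"})
#: Region categories counted as gene body.
BODY_CATEGORIES = frozenset({"1stExon", "ExonBnd", "Body", "3UTR"})
#: All admissible region categories; "intergenic" is exclusive of the rest.
REGION_CATEGORIES = PROMOTER_CATEGORIES | BODY_CATEGORIES | {"intergenic"}
ISLAND_STATUSES = ("Island", "Shore", "Shelf", "OpenSea")
TIMEPOINTS = ("d0", "d8", "d15")
CELL_TYPES = ("blast", "tcell")
RESPONSE_GROUPS = ("responder", "nonresponder", "unknown")
SEX_CHROMOSOMES = frozenset({"chrX", "chrY"})

#: Default clamping epsilon for the beta -> m logit transform.  Normalized
#: array betas never reach exactly 0/1, but synthetic or rounded data may;
#: clamping at 1e-3 keeps the transform finite while perturbing real
#: values negligibly (|m| capped near +-9.97).
DEFAULT_EPSILON = 1e-3


class ValidationError(ValueError):
    """Raised when an input object violates a container invariant."""


def _check_unique(values, what: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dup}")


def _first_offender(mask: np.ndarray, index, columns) -> str:
    i, j = np.argwhere(mask)[0]
    return f"row {index[i]!r}, column {columns[j]!r}"


class _FeatureMatrix:
    """Feature x sample numeric matrix with unique string axes."""

    _kind = "matrix"
    _feature_axis = "feature_ids"

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data, pd.DataFrame):
            data = pd.DataFrame(data)
        _check_unique(data.index, f"{self._kind} {self._feature_axis}")
        _check_unique(data.columns, f"{self._kind} sample_ids")
        values = data.to_numpy(dtype=float, copy=False)
        finite = np.isfinite(values)
        if not finite.all():
            where = _first_offender(~finite, data.index, data.columns)
            raise ValidationError(f"non-finite value in {self._kind} at {where}")
        self._validate_values(values, data)
        self.data = data

    def _validate_values(self, values: np.ndarray, data: pd.DataFrame) -> None:
        pass

    # -- axes -----------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self.data.shape
        return f"<{type(self).__name__} {n} x {m}>"

    def select_samples(self, sample_ids) -> "pd.DataFrame":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"sample(s) not in {self._kind}: {missing}")
        return self.data[list(sample_ids)]

    def subset_features(self, feature_ids) -> "_FeatureMatrix":
        missing = pd.Index(feature_ids).difference(self.data.index)
        if len(missing):
            raise ValidationError(
                f"unknown {self._feature_axis} requested: {list(missing[:5])}"
            )
        return type(self)(self.data.loc[list(feature_ids)])


class BetaMatrix(_FeatureMatrix):
    """CpG x sample methylation fractions, every value finite in [0, 1]."""

    _kind = "beta matrix"
    _feature_axis = "cpg_ids"

    def _validate_values(self, values, data):
        bad = (values < 0.0) | (values > 1.0)
        if bad.any():
            where = _first_offender(bad, data.index, data.columns)
            raise ValidationError(f"beta value outside [0, 1] at {where}")

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.data.index)

    def subset_cpgs(self, cpg_ids) -> "BetaMatrix":
        return self.subset_features(cpg_ids)


class MValueMatrix(_FeatureMatrix):
    """CpG x sample m-values: m = log2(beta / (1 - beta)), finite."""

    _kind = "m-value matrix"
    _feature_axis = "cpg_ids"

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.data.index)


class ExpressionMatrix(_FeatureMatrix):
    """Probe- or gene-level normalized log2 intensities, finite."""

    _kind = "expression matrix"


def beta_to_m(beta: BetaMatrix, epsilon: float = DEFAULT_EPSILON) -> MValueMatrix:
    """Logit2 transform of a beta matrix with clamping into [eps, 1-eps]."""
    if not 0.0 < epsilon < 0.5:
        raise ValueError(f"epsilon must be in (0, 0.5), got {epsilon}")
    b = np.clip(beta.data.to_numpy(dtype=float), epsilon, 1.0 - epsilon)
    m = np.log2(b / (1.0 - b))
    return MValueMatrix(pd.DataFrame(m, index=beta.data.index, columns=beta.data.columns))


def m_to_beta(m: MValueMatrix) -> BetaMatrix:
    """Inverse logit2: beta = 2^m / (1 + 2^m), numerically stable."""
    x = m.data.to_numpy(dtype=float)
    # expit formulated to avoid overflow for large |m|
    beta = np.where(x >= 0, 1.0 / (1.0 + np.exp2(-x)), np.exp2(x) / (1.0 + np.exp2(x)))
    return BetaMatrix(pd.DataFrame(beta, index=m.data.index, columns=m.data.columns))


# ---------------------------------------------------------------------------
# sample sheet & paired designs
# ---------------------------------------------------------------------------

SHEET_COLUMNS = ["sample_id", "patient_id", "timepoint", "cycle", "cell_type", "response_group"]


class SampleSheet:
    """Per-sample metadata: patient, timepoint (d0/d8/d15), cycle, cell type,
    clinical response group.  (patient, timepoint, cycle, cell_type) is unique.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in SHEET_COLUMNS if c not in table.columns]
        if missing:
            raise ValidationError(f"sample sheet missing column(s): {missing}")
        table = table[SHEET_COLUMNS].copy()
        table["cycle"] = table["cycle"].astype(int)
        _check_unique(table["sample_id"], "sample_id")
        for col, allowed in (
            ("timepoint", TIMEPOINTS),
            ("cell_type", CELL_TYPES),
            ("response_group", RESPONSE_GROUPS),
        ):
            bad = sorted(set(table[col]) - set(allowed))
            if bad:
                raise ValidationError(f"invalid {col} value(s): {bad}")
        if (table["cycle"] < 1).any():
            raise ValidationError("cycle must be >= 1")
        key = table[["patient_id", "timepoint", "cycle", "cell_type"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValidationError(f"duplicate (patient, timepoint, cycle, cell_type): {dup}")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples(self, timepoint=None, cycle=None, cell_type=None, patients=None) -> pd.DataFrame:
        t = self.table
        if timepoint is not None:
            t = t[t["timepoint"] == timepoint]
        if cycle is not None:
            t = t[t["cycle"] == int(cycle)]
        if cell_type is not None:
            t = t[t["cell_type"] == cell_type]
        if patients is not None:
            t = t[t["patient_id"].isin(set(patients))]
        return t

    def patients(self, cell_type=None, cycle=None) -> list[str]:
        return sorted(self.samples(cycle=cycle, cell_type=cell_type)["patient_id"].unique())

    def response_groups(self, cell_type: str = "blast") -> dict[str, str]:
        sub = self.samples(cell_type=cell_type)
        return dict(sub.drop_duplicates("patient_id")[["patient_id", "response_group"]].values)

    def paired_design(
        self, t1: str, t0: str, cycle: int = 1, cell_type: str = "blast", patients=None
    ) -> "PairedDesign":
        """Build the per-patient (t1, t0) column pairing for one contrast.

        Patients lacking either timepoint are silently excluded here;
        callers that must report them use :meth:`unpaired_patients`.
        """
        s1 = self.samples(timepoint=t1, cycle=cycle, cell_type=cell_type, patients=patients)
        s0 = self.samples(timepoint=t0, cycle=cycle, cell_type=cell_type, patients=patients)
        m1 = dict(s1[["patient_id", "sample_id"]].values)
        m0 = dict(s0[["patient_id", "sample_id"]].values)
        shared = sorted(set(m1) & set(m0))
        if not shared:
            raise ValidationError(
                f"no patient has both {t1} and {t0} (cycle {cycle}, {cell_type})"
            )
        return PairedDesign(
            patients=tuple(shared),
            t1_samples=tuple(m1[p] for p in shared),
            t0_samples=tuple(m0[p] for p in shared),
            t1=t1,
            t0=t0,
            cycle=int(cycle),
            cell_type=cell_type,
        )

    def unpaired_patients(self, t1, t0, cycle=1, cell_type="blast") -> list[str]:
        """Patients of this (cycle, cell_type) missing one of the two timepoints."""
        all_p = set(self.samples(cycle=cycle, cell_type=cell_type)["patient_id"])
        have1 = set(self.samples(timepoint=t1, cycle=cycle, cell_type=cell_type)["patient_id"])
        have0 = set(self.samples(timepoint=t0, cycle=cycle, cell_type=cell_type)["patient_id"])
        return sorted(all_p - (have1 & have0))


@dataclass(frozen=True)
class PairedDesign:
    """Per-patient (later, earlier) sample column pairs for one contrast."""

    patients: tuple[str, ...]
    t1_samples: tuple[str, ...]
    t0_samples: tuple[str, ...]
    t1: str = "d8"
    t0: str = "d0"
    cycle: int = 1
    cell_type: str = "blast"

    def __post_init__(self):
        if not (len(self.patients) == len(self.t1_samples) == len(self.t0_samples)):
            raise ValidationError("design arms have unequal lengths")
        _check_unique(self.patients, "design patients")

    @property
    def n(self) -> int:
        return len(self.patients)

    def label(self) -> str:
        return f"{self.cell_type}_c{self.cycle}_{self.t1}_vs_{self.t0}"


# ---------------------------------------------------------------------------
# CpG annotation
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "chromosome",
    "position",
    "nearest_gene",
    "tss_distance",
    "region_categories",
    "island_status",
    "repeat_overlap",
    "snp_overlap",
]


class CpGAnnotation:
    """Per-CpG genomic context.

    ``region_categories`` is a frozenset per CpG drawn from
    :data:`REGION_CATEGORIES`; a CpG may carry several genic categories
    (as on the array manifest) but "intergenic" is exclusive.
    Coordinates are 1-based; ``tss_distance`` is signed (CpG position
    minus TSS position, strand ignored).
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
        if missing:
            raise ValidationError(f"annotation missing column(s): {missing}")
        table = table[ANNOTATION_COLUMNS].copy()
        _check_unique(table.index, "annotation cpg_id")
        table["position"] = table["position"].astype(int)
        table["tss_distance"] = table["tss_distance"].astype(int)
        table["repeat_overlap"] = table["repeat_overlap"].astype(bool)
        table["snp_overlap"] = table["snp_overlap"].astype(bool)
        cats = table["region_categories"].map(frozenset)
        for cpg, cs in cats.items():
            if not cs:
                raise ValidationError(f"{cpg}: empty region_categories")
            unknown = cs - REGION_CATEGORIES
            if unknown:
                raise ValidationError(f"{cpg}: unknown region categories {sorted(unknown)}")
            if "intergenic" in cs and len(cs) > 1:
                raise ValidationError(f"{cpg}: intergenic must be exclusive")
        table["region_categories"] = cats
        bad = sorted(set(table["island_status"]) - set(ISLAND_STATUSES))
        if bad:
            raise ValidationError(f"invalid island_status value(s): {bad}")
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.table.index)

    def for_cpgs(self, cpg_ids) -> "CpGAnnotation":
        missing = pd.Index(cpg_ids).difference(self.table.index)
        if len(missing):
            raise ValidationError(f"unannotated CpG id(s): {list(missing[:5])}")
        out = CpGAnnotation.__new__(CpGAnnotation)
        out.table = self.table.loc[list(cpg_ids)]
        return out

    def has_category(self, category: str) -> pd.Series:
        return self.table["region_categories"].map(lambda s: category in s)

    def region_mask(self, categories) -> pd.Series:
        cats = frozenset(categories)
        return self.table["region_categories"].map(lambda s: bool(s & cats))

    def promoter_mask(self) -> pd.Series:
        return self.region_mask(PROMOTER_CATEGORIES)

    def body_mask(self) -> pd.Series:
        return self.region_mask(BODY_CATEGORIES)


def filter_cpgs(beta: BetaMatrix, annot: CpGAnnotation) -> BetaMatrix:
    """Drop CpGs on chrX/chrY and CpGs overlapping known SNPs.

    Every CpG in ``beta`` must be annotated; order of the retained CpGs is
    preserved.  Idempotent.
    """
    sub = annot.for_cpgs(beta.cpg_ids).table
    keep = (~sub["chromosome"].isin(SEX_CHROMOSOMES)) & (~sub["snp_overlap"])
    return BetaMatrix(beta.data.loc[keep.to_numpy()])


def annotate_nearest_gene(positions: pd.DataFrame, tss_table: pd.DataFrame) -> pd.DataFrame:
    """Assign each CpG its nearest gene by absolute TSS distance.

    Parameters
    ----------
    positions : DataFrame indexed by cpg_id with columns ``chromosome``,
        ``position`` (1-based bp).
    tss_table : DataFrame with columns ``gene_id``, ``chromosome``, ``tss``.

    Returns
    -------
    DataFrame indexed like ``positions`` with columns ``nearest_gene`` and
    signed ``tss_distance`` (CpG position minus TSS; negative means the CpG
    lies 5' of the TSS in reference orientation — strand is ignored).
    Equidistant ties break to the lexicographically smallest gene id.
    """
    for col in ("chromosome", "position"):
        if col not in positions.columns:
            raise ValidationError(f"positions table missing column {col!r}")
    for col in ("gene_id", "chromosome", "tss"):
        if col not in tss_table.columns:
            raise ValidationError(f"tss table missing column {col!r}")

    genes = np.empty(len(positions), dtype=object)
    dists = np.zeros(len(positions), dtype=np.int64)
    chrom_arr = positions["chromosome"].to_numpy()
    pos_arr = positions["position"].to_numpy(dtype=np.int64)

    for chrom in pd.unique(chrom_arr):
        sel = np.flatnonzero(chrom_arr == chrom)
        sub = tss_table[tss_table["chromosome"] == chrom]
        if sub.empty:
            cpg = positions.index[sel[0]]
            raise ValidationError(f"no TSS entries on {chrom} (CpG {cpg!r})")
        gene_ids = sub["gene_id"].to_numpy(dtype=object)
        tss = sub["tss"].to_numpy(dtype=np.int64)
        # sort by (position, gene id): within an equal-position block the
        # lexicographically smallest gene comes first
        order = np.lexsort((gene_ids, tss))
        tss_s, genes_s = tss[order], gene_ids[order]

        cp = pos_arr[sel]
        idx = np.searchsorted(tss_s, cp)  # leftmost TSS >= CpG
        right = np.minimum(idx, len(tss_s) - 1)
        left_last = np.maximum(idx - 1, 0)
        # first entry of the equal-position block left of the CpG, so that
        # ties among co-located genes resolve to the smallest gene id
        left = np.searchsorted(tss_s, tss_s[left_last])
        d_right = np.abs(cp - tss_s[right])
        d_left = np.abs(cp - tss_s[left])
        has_right = idx < len(tss_s)
        has_left = idx > 0

        use_left = has_left & (
            ~has_right
            | (d_left < d_right)
            | ((d_left == d_right) & (genes_s[left] < genes_s[right]))
        )
        best = np.where(use_left, left, right)
        genes[sel] = genes_s[best]
        dists[sel] = cp - tss_s[best]

    return pd.DataFrame({"nearest_gene": genes, "tss_distance": dists}, index=positions.index)
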