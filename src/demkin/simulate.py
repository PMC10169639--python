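"""Synthetic serial-methylome cohort generator with a ground-truth record.

The generator emulates the statistical structure of a decitabine-treated
AML cohort profiled on a 450K-style array at days 0, 8 and 15, scaled to
desk size:

* a bimodal baseline methylome (heavily methylated ~0.9 and unmethylated
  ~0.1 modes; the heavy mode dominates, so the cohort median sits near 0.9);
* a planted *signature*: a CpG set demethylated in every blast patient at
  day 8 of every cycle, preferentially drawn from open-sea/repeat context;
* per-patient *background* demethylation at a patient-specific rate
  (drawn from a wide range, emulating the striking inter-patient
  variability of the in-vivo response), by default preferentially hitting
  heavily methylated CpGs;
* partial, per-patient-random remethylation at day 15: a configurable
  fraction of each patient's demethylated CpGs rebounds, restoring a
  uniform random 30-100% of the day-8 deficit;
* near-null T-cell effects: small per-patient random sets with no common
  structure;
* a planted set of genes whose expression induction anti-correlates with
  their promoter demethylation across patients.

Beta values are observed through beta-distributed measurement noise
centred on the latent mean, which keeps every emitted value inside [0, 1]
without clipping artefacts.  One pseudo-random stream per logical
component (annotation, baseline, effects, remethylation, T-cells,
expression, noise, ...) is derived from the master seed, so tests can
perturb one component in isolation.  Identical config + seed gives
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .datamodel import (
    BetaMatrix,
    CpGAnnotation,
    ExpressionMatrix,
    SampleSheet,
    annotate_nearest_gene,
)
from .diffmeth import classify_demethylation_magnitude

#: Size of the full 450K universe after chrX/chrY + SNP filtering; used to
#: scale the strong/limited response bin boundaries to the simulated size.
FULL_ARRAY_CPGS = 456_281

_GENE_CPG_PLAN = (
    # (offset from TSS, region categories)
    (-1200, ("TSS1500",)),
    (-150, ("TSS200",)),
    (60, ("5UTR",)),
    (5000, ("1stExon",)),
    (20000, ("Body",)),
)


@dataclass
class CohortConfig:
    """Generation parameters; defaults are the package's study conditions."""

    n_cpgs: int = 20_000
    n_genes: int = 2_000
    n_patients_blast: int = 12
    n_patients_tcell: int = 8
    n_cycle2_patients: int = 6

    # baseline methylome
    hyper_fraction: float = 0.8
    baseline_modes: tuple[float, float] = (0.9, 0.1)
    baseline_concentration: float = 50.0

    # planted common-demethylation signature
    signature_size: int = 100
    signature_effect: float = -0.3
    signature_context_bias: float = 3.0  # selection weight boost for open-sea/repeat CpGs

    # per-patient background demethylation
    per_patient_background_rate: tuple[float, float] = (0.02, 0.35)
    background_effect: float = -0.25
    background_selection: str = "baseline_weighted"  # or "uniform"

    # day-15 rebound
    remethylation_fraction: float = 0.5
    partial_restore_range: tuple[float, float] = (0.3, 1.0)

    # bystander T cells
    tcell_effect_rate: float = 0.005
    tcell_effect: float = -0.25

    # expression + planted anti-correlation
    n_anticorr_genes: int = 50
    anticorr_slope: float = -4.0
    anticorr_delta_range: tuple[float, float] = (-0.25, 0.0)
    expression_noise_sd: float = 0.3
    expression_baseline_mean: float = 7.0
    expression_baseline_sd: float = 1.5
    expression_technical_sd: float = 0.1

    # array-like measurement noise (beta re-draw concentration); 600 gives
    # a technical sd of ~0.02 at mid-range beta and ~0.012 at beta=0.9,
    # matching 450K replicate dispersion
    measurement_noise_concentration: float = 600.0

    # annotation make-up
    xy_fraction: float = 0.02
    snp_fraction: float = 0.02
    repeat_fraction: float = 0.15

    responder_fraction: float = 0.45
    seed: int = 0

    def validate(self) -> None:
        c = self
        if c.n_genes < 3:
            raise ValueError("n_genes must be >= 3")
        if c.n_cpgs < len(_GENE_CPG_PLAN) * c.n_genes:
            raise ValueError(
                f"n_cpgs must be >= {len(_GENE_CPG_PLAN)} * n_genes "
                f"({len(_GENE_CPG_PLAN) * c.n_genes})"
            )
        if c.signature_size > c.n_cpgs:
            raise ValueError("signature_size exceeds n_cpgs")
        if c.n_anticorr_genes > c.n_genes:
            raise ValueError("n_anticorr_genes exceeds n_genes")
        if not 1 <= c.n_patients_blast:
            raise ValueError("need at least one blast patient")
        if c.n_patients_tcell > c.n_patients_blast:
            raise ValueError("T-cell patients are a subset of blast patients")
        if c.n_cycle2_patients > c.n_patients_blast:
            raise ValueError("cycle-2 patients are a subset of blast patients")
        for name in (
            "hyper_fraction",
            "remethylation_fraction",
            "tcell_effect_rate",
            "xy_fraction",
            "snp_fraction",
            "repeat_fraction",
            "responder_fraction",
        ):
            v = getattr(c, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = c.per_patient_background_rate
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("per_patient_background_rate must be an ordered range in [0, 1]")
        if c.background_selection not in ("baseline_weighted", "uniform"):
            raise ValueError("background_selection must be 'baseline_weighted' or 'uniform'")
        for name in ("signature_effect", "background_effect", "tcell_effect"):
            if getattr(c, name) >= 0:
                raise ValueError(f"{name} must be negative (demethylation)")
        if c.measurement_noise_concentration <= 0 or c.baseline_concentration <= 0:
            raise ValueError("concentration parameters must be > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        kwargs = dict(d)
        for key in ("baseline_modes", "per_patient_background_rate",
                    "partial_restore_range", "anticorr_delta_range"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        unknown = set(kwargs) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown cohort config key(s): {sorted(unknown)}")
        return cls(**kwargs)


@dataclass
class CohortTruth:
    """Ground-truth record, consistent with the emitted matrices by
    construction; the oracle for downstream tests."""

    signature_cpg_ids: set
    anticorrelated_gene_ids: set
    demethylated_d8: dict          # blast cycle 1: patient -> CpG set
    remethylated_d15: dict         # blast cycle 1: patient -> CpG set
    demethylated_d8_cycle2: dict   # blast cycle 2: patient -> CpG set
    tcell_demethylated_d8: dict    # patient -> CpG set
    background_rate: dict          # patient -> cycle-1 background rate
    magnitude_category: dict       # patient -> strong/intermediate/limited
    magnitude_thresholds: tuple    # (strong, limited), scaled to n_cpgs
    anticorr_delta: dict           # gene -> patient -> planted promoter delta
    retained_cpg_ids: set          # CpGs surviving chrX/chrY + SNP filtering

    def to_json_dict(self) -> dict:
        def setlist(s):
            return sorted(s)

        return {
            "signature_cpg_ids": setlist(self.signature_cpg_ids),
            "anticorrelated_gene_ids": setlist(self.anticorrelated_gene_ids),
            "demethylated_d8": {p: setlist(s) for p, s in self.demethylated_d8.items()},
            "remethylated_d15": {p: setlist(s) for p, s in self.remethylated_d15.items()},
            "demethylated_d8_cycle2": {
                p: setlist(s) for p, s in self.demethylated_d8_cycle2.items()
            },
            "tcell_demethylated_d8": {
                p: setlist(s) for p, s in self.tcell_demethylated_d8.items()
            },
            "background_rate": self.background_rate,
            "magnitude_category": self.magnitude_category,
            "magnitude_thresholds": list(self.magnitude_thresholds),
            "anticorr_delta": self.anticorr_delta,
            "retained_cpg_ids": setlist(self.retained_cpg_ids),
        }


@dataclass
class Cohort:
    """Bundle of everything one simulation emits."""

    beta: BetaMatrix
    expression: ExpressionMatrix
    annotation: CpGAnnotation
    sheet: SampleSheet
    truth: CohortTruth
    config: CohortConfig


def _weighted_sample_without_replacement(rng, indices, weights, k):
    """Efraimidis-Spirakis exponential-key weighted sampling without
    replacement: the k items with the smallest Exp(1)/w keys."""
    if k <= 0:
        return indices[:0]
    if k > len(indices):
        raise ValueError("sample size exceeds population")
    keys = rng.exponential(size=len(indices)) / weights
    take = np.argpartition(keys, k - 1)[:k]
    return indices[take]


def _observe(rng, latent, concentration):
    """Draw observed betas around the latent mean with given concentration."""
    m = np.clip(latent, 1e-3, 1.0 - 1e-3)
    return rng.beta(m * concentration, (1.0 - m) * concentration)


def simulate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate a full synthetic cohort; see the module docstring.

    ``seed`` overrides ``config.seed`` when given.
    """
    cfg = config or CohortConfig()
    if seed is not None:
        cfg = CohortConfig.from_dict({**asdict(cfg), "seed": int(seed)})
    cfg.validate()

    streams = np.random.SeedSequence(cfg.seed).spawn(9)
    rng_annot, rng_base, rng_resp, rng_fx, rng_remeth, rng_c2, rng_tcell, rng_expr, rng_noise = [
        np.random.default_rng(s) for s in streams
    ]

    # ------------------------------------------------------------------
    # annotation: genes, CpG layout, context, flags
    # ------------------------------------------------------------------
    n_genes, n_cpgs = cfg.n_genes, cfg.n_cpgs
    per_gene = len(_GENE_CPG_PLAN)
    n_xy = int(round(cfg.xy_fraction * n_cpgs))
    gene_ids = np.array([f"G{i:05d}" for i in range(1, n_genes + 1)], dtype=object)
    autosomes = [f"chr{i}" for i in range(1, 23)]
    gene_chrom = np.array([autosomes[i % 22] for i in range(n_genes)], dtype=object)
    if n_xy > 0:
        gene_chrom[-2], gene_chrom[-1] = "chrX", "chrY"
    # TSS spacing 200 kb within each chromosome
    gene_tss = np.zeros(n_genes, dtype=np.int64)
    per_chrom_counter: dict[str, int] = {}
    for i in range(n_genes):
        k = per_chrom_counter.get(gene_chrom[i], 0)
        per_chrom_counter[gene_chrom[i]] = k + 1
        gene_tss[i] = 50_000 + k * 200_000
    tss_table = pd.DataFrame({"gene_id": gene_ids, "chromosome": gene_chrom, "tss": gene_tss})

    cpg_chrom = np.empty(n_cpgs, dtype=object)
    cpg_pos = np.zeros(n_cpgs, dtype=np.int64)
    cpg_cats = np.empty(n_cpgs, dtype=object)
    owner_gene = np.empty(n_cpgs, dtype=object)  # None for intergenic
    j = 0
    for g in range(n_genes):
        for off, cats in _GENE_CPG_PLAN:
            cpg_chrom[j] = gene_chrom[g]
            cpg_pos[j] = gene_tss[g] + off
            # an occasional multi-category CpG, as on the array manifest
            if cats == ("TSS200",) and g % 7 == 0:
                cpg_cats[j] = frozenset({"TSS200", "5UTR"})
            else:
                cpg_cats[j] = frozenset(cats)
            owner_gene[j] = gene_ids[g]
            j += 1
    n_intergenic = n_cpgs - j
    # intergenic CpGs scattered between gene loci; some on chrX/chrY
    n_xy_intergenic = min(n_intergenic, max(0, n_xy - (per_gene * 2 if n_xy > 0 else 0)))
    # intergenic CpGs only on chromosomes that host a gene, so every CpG
    # has a nearest-TSS assignment
    used_autosomes = [c for c in autosomes if c in set(gene_chrom)]
    inter_chrom = np.array(
        [used_autosomes[i % len(used_autosomes)] for i in range(n_intergenic - n_xy_intergenic)]
        + ["chrX" if i % 2 == 0 else "chrY" for i in range(n_xy_intergenic)],
        dtype=object,
    )
    max_pos = 50_000 + (max(per_chrom_counter.values()) + 1) * 200_000
    inter_pos = rng_annot.integers(1, max_pos, size=n_intergenic)
    cpg_chrom[j:] = inter_chrom
    cpg_pos[j:] = inter_pos
    for t in range(j, n_cpgs):
        cpg_cats[t] = frozenset({"intergenic"})
        owner_gene[t] = None
    is_gene_cpg = np.array([o is not None for o in owner_gene])

    cpg_ids = np.array([f"cg{i:08d}" for i in range(1, n_cpgs + 1)], dtype=object)
    positions = pd.DataFrame({"chromosome": cpg_chrom, "position": cpg_pos}, index=cpg_ids)
    nearest = annotate_nearest_gene(positions, tss_table)

    island = np.empty(n_cpgs, dtype=object)
    prom_mask = np.array([bool(c & {"TSS1500", "TSS200", "5UTR"}) for c in cpg_cats])
    body_only = is_gene_cpg & ~prom_mask
    inter_mask = ~is_gene_cpg
    island[prom_mask] = rng_annot.choice(
        ["Island", "Shore", "Shelf", "OpenSea"], size=prom_mask.sum(), p=[0.7, 0.2, 0.05, 0.05]
    )
    island[body_only] = rng_annot.choice(
        ["Island", "Shore", "Shelf", "OpenSea"], size=body_only.sum(), p=[0.1, 0.2, 0.2, 0.5]
    )
    island[inter_mask] = rng_annot.choice(
        ["Island", "Shore", "Shelf", "OpenSea"], size=inter_mask.sum(), p=[0.03, 0.07, 0.15, 0.75]
    )
    repeat_p = np.where(inter_mask, min(1.0, 2.0 * cfg.repeat_fraction), cfg.repeat_fraction)
    repeat = rng_annot.random(n_cpgs) < repeat_p
    snp = rng_annot.random(n_cpgs) < cfg.snp_fraction

    annot = CpGAnnotation(
        pd.DataFrame(
            {
                "chromosome": cpg_chrom,
                "position": cpg_pos,
                "nearest_gene": nearest["nearest_gene"].to_numpy(),
                "tss_distance": nearest["tss_distance"].to_numpy(),
                "region_categories": cpg_cats,
                "island_status": island,
                "repeat_overlap": repeat,
                "snp_overlap": snp,
            },
            index=pd.Index(cpg_ids, name="cpg_id"),
        )
    )

    retained = (~np.isin(cpg_chrom, ["chrX", "chrY"])) & (~snp)

    # ------------------------------------------------------------------
    # baseline methylome
    # ------------------------------------------------------------------
    hyper = rng_base.random(n_cpgs) < cfg.hyper_fraction
    mode = np.where(hyper, cfg.baseline_modes[0], cfg.baseline_modes[1])
    c0 = cfg.baseline_concentration
    baseline = rng_base.beta(mode * c0, (1.0 - mode) * c0)
    baseline = np.clip(baseline, 0.02, 0.98)

    # ------------------------------------------------------------------
    # planted structure: anti-correlated genes, then the signature
    # ------------------------------------------------------------------
    gene_of = pd.Series(owner_gene, index=cpg_ids)
    promoter_idx_of_gene: dict[str, np.ndarray] = {}
    for g in range(n_genes):
        lo = g * per_gene
        promoter_idx_of_gene[gene_ids[g]] = np.flatnonzero(prom_mask[lo : lo + per_gene]) + lo

    eligible_genes = [
        gid
        for g, gid in enumerate(gene_ids)
        if retained[promoter_idx_of_gene[gid]].all() and gene_chrom[g] not in ("chrX", "chrY")
    ]
    if cfg.n_anticorr_genes > len(eligible_genes):
        raise ValueError(
            f"only {len(eligible_genes)} genes have fully retained promoters; "
            f"cannot plant {cfg.n_anticorr_genes} anti-correlated genes"
        )
    anticorr_genes = set(
        rng_fx.choice(np.array(eligible_genes, dtype=object),
                      size=cfg.n_anticorr_genes, replace=False)
    )
    anticorr_prom_idx = np.concatenate(
        [promoter_idx_of_gene[g] for g in sorted(anticorr_genes)]
    ) if anticorr_genes else np.array([], dtype=int)
    # guarantee demethylation headroom at planted promoters
    if anticorr_prom_idx.size:
        baseline[anticorr_prom_idx] = np.clip(
            rng_fx.beta(cfg.baseline_modes[0] * c0, (1 - cfg.baseline_modes[0]) * c0,
                        size=anticorr_prom_idx.size),
            0.6, 0.98,
        )
    is_anticorr_prom = np.zeros(n_cpgs, dtype=bool)
    is_anticorr_prom[anticorr_prom_idx] = True

    sig_pool = np.flatnonzero(retained & hyper & ~is_anticorr_prom)
    if cfg.signature_size > sig_pool.size:
        raise ValueError(
            f"signature_size {cfg.signature_size} exceeds the eligible pool ({sig_pool.size})"
        )
    sig_w = np.ones(sig_pool.size)
    boost = (island[sig_pool] == "OpenSea") | repeat[sig_pool]
    sig_w[boost] = cfg.signature_context_bias
    sig_idx = np.sort(
        _weighted_sample_without_replacement(rng_fx, sig_pool, sig_w, cfg.signature_size)
    )
    signature_ids = set(cpg_ids[sig_idx])

    # ------------------------------------------------------------------
    # patients, response groups
    # ------------------------------------------------------------------
    patients = [f"P{i:02d}" for i in range(1, cfg.n_patients_blast + 1)]
    tcell_patients = patients[: cfg.n_patients_tcell]
    c2_patients = patients[: cfg.n_cycle2_patients]
    n_resp = int(round(cfg.responder_fraction * len(patients)))
    resp_idx = set(rng_resp.choice(len(patients), size=n_resp, replace=False).tolist())
    response = {
        p: ("responder" if i in resp_idx else "nonresponder") for i, p in enumerate(patients)
    }

    # ------------------------------------------------------------------
    # per-patient latent trajectories (blast, cycle 1 and 2; T cells)
    # ------------------------------------------------------------------
    bg_pool = np.flatnonzero(retained & ~is_anticorr_prom)
    bg_pool = bg_pool[~np.isin(bg_pool, sig_idx)]
    if cfg.background_selection == "baseline_weighted":
        bg_weights = baseline[bg_pool]
    else:
        bg_weights = np.ones(bg_pool.size)

    scale = n_cpgs / FULL_ARRAY_CPGS
    strong_thr = int(round(100_000 * scale))
    limited_thr = int(round(25_000 * scale))

    latent_cols: dict[str, np.ndarray] = {}
    sheet_rows: list[dict] = []
    truth_d8: dict[str, set] = {}
    truth_remeth: dict[str, set] = {}
    truth_d8_c2: dict[str, set] = {}
    truth_tcell: dict[str, set] = {}
    truth_rate: dict[str, float] = {}
    truth_mag: dict[str, str] = {}
    anticorr_delta: dict[str, dict[str, float]] = {g: {} for g in sorted(anticorr_genes)}

    def add_sample(patient, tp, cycle, cell_type, latent):
        sid = f"{patient}_c{cycle}_{tp}_{cell_type}"
        latent_cols[sid] = latent
        sheet_rows.append(
            {
                "sample_id": sid,
                "patient_id": patient,
                "timepoint": tp,
                "cycle": cycle,
                "cell_type": cell_type,
                "response_group": response[patient],
            }
        )
        return sid

    def apply_cycle_effects(rng, patient, record_delta: bool):
        """Latent day-8 methylome for one patient and cycle; returns
        (latent, demethylated index array)."""
        latent = baseline.copy()
        latent[sig_idx] += cfg.signature_effect
        lo, hi = cfg.per_patient_background_rate
        rate = float(rng.uniform(lo, hi))
        n_bg = int(round(rate * bg_pool.size))
        bg_sel = _weighted_sample_without_replacement(rng, bg_pool, bg_weights, n_bg)
        latent[bg_sel] += cfg.background_effect
        for g in sorted(anticorr_genes):
            d = float(rng.uniform(*cfg.anticorr_delta_range))
            latent[promoter_idx_of_gene[g]] += d
            if record_delta:
                anticorr_delta[g][patient] = d
        np.clip(latent, 0.02, 0.98, out=latent)
        demeth = np.flatnonzero(latent < baseline - 1e-9)
        return latent, demeth, rate

    for patient in patients:
        add_sample(patient, "d0", 1, "blast", baseline)
        latent_d8, demeth, rate = apply_cycle_effects(rng_fx, patient, record_delta=True)
        add_sample(patient, "d8", 1, "blast", latent_d8)
        truth_d8[patient] = set(cpg_ids[demeth])
        truth_rate[patient] = rate
        truth_mag[patient] = classify_demethylation_magnitude(
            demeth.size, strong_threshold=strong_thr, limited_threshold=limited_thr
        )

        # day-15 rebound
        n_rebound = int(round(cfg.remethylation_fraction * demeth.size))
        rebound = rng_remeth.choice(demeth, size=n_rebound, replace=False)
        latent_d15 = latent_d8.copy()
        restore = rng_remeth.uniform(*cfg.partial_restore_range, size=n_rebound)
        latent_d15[rebound] += restore * (baseline[rebound] - latent_d8[rebound])
        add_sample(patient, "d15", 1, "blast", latent_d15)
        truth_remeth[patient] = set(cpg_ids[np.sort(rebound)])

    for patient in c2_patients:
        add_sample(patient, "d0", 2, "blast", baseline)
        latent_d8, demeth, _ = apply_cycle_effects(rng_c2, patient, record_delta=False)
        add_sample(patient, "d8", 2, "blast", latent_d8)
        truth_d8_c2[patient] = set(cpg_ids[demeth])

    tcell_pool = np.flatnonzero(retained)
    for patient in tcell_patients:
        add_sample(patient, "d0", 1, "tcell", baseline)
        n_fx = int(round(cfg.tcell_effect_rate * tcell_pool.size))
        sel = rng_tcell.choice(tcell_pool, size=n_fx, replace=False)
        latent = baseline.copy()
        latent[sel] += cfg.tcell_effect
        np.clip(latent, 0.02, 0.98, out=latent)
        add_sample(patient, "d8", 1, "tcell", latent)
        truth_tcell[patient] = set(cpg_ids[np.sort(sel)])

    # ------------------------------------------------------------------
    # observation noise
    # ------------------------------------------------------------------
    observed = {
        sid: _observe(rng_noise, latent, cfg.measurement_noise_concentration)
        for sid, latent in latent_cols.items()
    }
    beta = BetaMatrix(pd.DataFrame(observed, index=pd.Index(cpg_ids, name="id")))

    # ------------------------------------------------------------------
    # expression (blast cycle 1, d0 and d8; gene-level features)
    # ------------------------------------------------------------------
    gene_baseline = rng_expr.normal(
        cfg.expression_baseline_mean, cfg.expression_baseline_sd, size=n_genes
    )
    expr_cols: dict[str, np.ndarray] = {}
    gene_index = pd.Index(gene_ids, name="id")
    gene_pos = {g: k for k, g in enumerate(gene_ids)}
    for patient in patients:
        d0 = gene_baseline + rng_expr.normal(0.0, cfg.expression_technical_sd, size=n_genes)
        fc = rng_expr.normal(0.0, cfg.expression_noise_sd, size=n_genes)
        for g in sorted(anticorr_genes):
            fc[gene_pos[g]] += cfg.anticorr_slope * anticorr_delta[g][patient]
        expr_cols[f"{patient}_c1_d0_blast"] = d0
        expr_cols[f"{patient}_c1_d8_blast"] = d0 + fc
    expression = ExpressionMatrix(pd.DataFrame(expr_cols, index=gene_index))

    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    truth = CohortTruth(
        signature_cpg_ids=signature_ids,
        anticorrelated_gene_ids=set(anticorr_genes),
        demethylated_d8=truth_d8,
        remethylated_d15=truth_remeth,
        demethylated_d8_cycle2=truth_d8_c2,
        tcell_demethylated_d8=truth_tcell,
        background_rate=truth_rate,
        magnitude_category=truth_mag,
        magnitude_thresholds=(strong_thr, limited_thr),
        anticorr_delta=anticorr_delta,
        retained_cpg_ids=set(cpg_ids[retained]),
    )
    return Cohort(
        beta=beta,
        expression=expression,
        annotation=annot,
        sheet=sheet,
        truth=truth,
        config=cfg,
    )


def write_cohort(cohort: Cohort, out_dir) -> dict[str, str]:
    """Write all cohort artefacts in the package's text formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": out / "beta.tsv",
        "expression": out / "expression.tsv",
        "annotation": out / "annotation.tsv",
        "sheet": out / "samples.csv",
        "truth": out / "truth.json",
        "config": out / "cohort_config.json",
    }
    dio.write_matrix(cohort.beta, paths["beta"])
    dio.write_matrix(cohort.expression, paths["expression"])
    dio.write_annotation(cohort.annotation, paths["annotation"])
    dio.write_sample_sheet(cohort.sheet, paths["sheet"])
    dio.write_json(cohort.truth.to_json_dict(), paths["truth"])
    dio.write_json(asdict(cohort.config), paths["config"])
    return {k: str(v) for k, v in paths.items()}
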