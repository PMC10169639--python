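"""End-to-end orchestration: simulate/load -> filter -> differential
methylation per contrast -> signature null -> remethylation -> cycle
concordance -> T-cell contrast -> responder screen -> expression
integration -> context enrichment.

Every stage writes a self-describing TSV (leading comment line with
version, seed and parameters) into the output directory and is recorded
in ``manifest.json``.  Identical config + seed gives byte-identical
result tables.  A stage failure aborts the run with the stage name;
tables already written stay on disk.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as dio
from .datamodel import BetaMatrix, CpGAnnotation, SampleSheet, filter_cpgs
from .diffmeth import (
    PairedDifferentialModel,
    classify_demethylation_magnitude,
    cohort_methylation_summary,
    single_sample_delta_sets,
)
from .enrich import context_enrichment
from .integrate import (
    AntiCorrelationScreen,
    collapse_probes_by_iqr,
    gene_region_beta,
    paired_deg,
)
from .signature import (
    SignatureNullModel,
    SignatureNullResult,
    cycle_overlap,
    responder_screen,
    signature_enrichment_per_sample,
)
from .simulate import FULL_ARRAY_CPGS, CohortConfig, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """One-file configuration of a full pipeline run."""

    simulate: CohortConfig | None = None
    paths: dict | None = None          # beta, sheet, annotation, [expression, probe_map]
    alpha: float = 0.05
    delta_threshold: float = 0.1
    partial_delta: float = 0.075       # partial-remethylation delta threshold
    n_iterations: int = 1000
    min_fraction: float = 1.0
    screen_alpha: float = 0.05
    responder_hi: float = 0.8
    responder_lo: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if (self.simulate is None) == (self.paths is None):
            raise ValueError("config must give exactly one of 'simulate' or 'paths'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = CohortConfig.from_dict(sim)
        unknown = set(raw) - {f for f in cls.__dataclass_fields__ if f != "simulate"}
        if unknown:
            raise ValueError(f"unknown run config key(s): {sorted(unknown)}")
        return cls(simulate=sim, **raw)

    def params(self) -> dict:
        return {
            "alpha": self.alpha,
            "delta_threshold": self.delta_threshold,
            "partial_delta": self.partial_delta,
            "n_iterations": self.n_iterations,
            "min_fraction": self.min_fraction,
            "screen_alpha": self.screen_alpha,
            "responder_hi": self.responder_hi,
            "responder_lo": self.responder_lo,
            "seed": self.seed,
        }


@dataclass
class RemethylationResult:
    """Day-15 rebound of day-8-demethylated CpGs.

    ``per_patient_fraction`` is the mean over patients of the fraction of
    that patient's day-8 set with single-sample delta(d15 - d8) above the
    partial threshold — the direct estimator of a per-patient rebound
    rate.  ``group_fraction`` applies the group-wise moderated caller in
    the + direction to the group day-8 set instead; under
    patient-independent rebound it detects *any* patient rebounding and
    so runs higher.  ``null`` tests the per-patient remethylated sets for
    common (non-random) structure.
    """

    per_patient_sets: dict
    per_patient_fraction: float
    group_remethylated_set: set
    group_fraction: float
    null: SignatureNullResult


def remethylation_analysis(
    beta: BetaMatrix,
    sheet: SampleSheet,
    d8_sets: dict,
    group_d8_set: set,
    universe,
    alpha: float = 0.05,
    partial_delta: float = 0.075,
    n_iterations: int = 1000,
    seed: int | None = None,
    cycle: int = 1,
    cell_type: str = "blast",
) -> RemethylationResult:
    """Quantify and null-test remethylation between day 8 and day 15."""
    if not group_d8_set and not any(d8_sets.values()):
        raise ValueError("empty day-8 demethylated set")
    gain_sets, _ = single_sample_delta_sets(
        beta, sheet, "d15", "d8", cycle=cycle, cell_type=cell_type,
        delta_threshold=partial_delta, direction="hyper",
    )
    per_patient = {}
    fractions = []
    for patient, d8 in d8_sets.items():
        if patient not in gain_sets:
            continue
        remeth = set(d8) & gain_sets[patient]
        per_patient[patient] = remeth
        if d8:
            fractions.append(len(remeth) / len(d8))
    if not per_patient:
        raise ValueError("no patient has both day-8 calls and a day-15 sample")

    design = sheet.paired_design("d15", "d8", cycle=cycle, cell_type=cell_type)
    model = PairedDifferentialModel(beta, design)
    res = model.fit(alpha=alpha, delta_threshold=partial_delta)
    group_remeth = res.remethylated_set() & set(group_d8_set)
    group_frac = len(group_remeth) / len(group_d8_set) if group_d8_set else float("nan")

    null = SignatureNullModel(per_patient, universe).fit(n_iterations=n_iterations, seed=seed)
    return RemethylationResult(
        per_patient_sets=per_patient,
        per_patient_fraction=float(np.mean(fractions)) if fractions else float("nan"),
        group_remethylated_set=group_remeth,
        group_fraction=group_frac,
        null=null,
    )


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    """Manifest plus in-memory stage objects for programmatic use."""

    manifest: dict
    objects: dict = field(repr=False, default_factory=dict)

    def stage_names(self) -> list[str]:
        return [s["name"] for s in self.manifest["stages"]]


def _stage_seed(master: int, k: int) -> int:
    """Deterministic per-stage 31-bit seed derived from the master seed."""
    return int(np.random.SeedSequence([int(master), k]).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig, out_dir) -> PipelineResult:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.params()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": dict(params),
        "stages": [],
    }
    objects: dict = {}
    current = "setup"

    def done(name: str, rows: int, outputs: list[str], **extra) -> None:
        manifest["stages"].append({"name": name, "rows": int(rows), "outputs": outputs, **extra})
        logger.info("stage %s done (%d rows)", name, rows)

    def skip(name: str, reason: str) -> None:
        manifest["skipped"] = manifest.get("skipped", [])
        manifest["skipped"].append({"name": name, "reason": reason})
        logger.info("stage %s skipped: %s", name, reason)

    t_start = time.perf_counter()
    try:
        # -- cohort --------------------------------------------------------
        current = "cohort"
        if config.simulate is not None:
            cohort = simulate_cohort(config.simulate, seed=config.seed)
            paths = write_cohort(cohort, out / "cohort")
            beta, sheet, annot = cohort.beta, cohort.sheet, cohort.annotation
            expr = cohort.expression
            objects["cohort"] = cohort
            done("cohort", len(beta.cpg_ids), sorted(paths.values()))
        else:
            p = config.paths
            beta, sheet, annot = dio.load_dataset(p["beta"], p["sheet"], p["annotation"])
            expr = dio.read_expression_matrix(p["expression"]) if p.get("expression") else None
            if expr is not None and p.get("probe_map"):
                pm = pd.read_csv(p["probe_map"], sep="\t", index_col=0).iloc[:, 0]
                expr = collapse_probes_by_iqr(expr, pm)
            done("cohort", len(beta.cpg_ids), [str(p["beta"])])

        # -- filter --------------------------------------------------------
        current = "filter"
        filtered = filter_cpgs(beta, annot)
        if not filtered.cpg_ids:
            raise ValueError("no CpGs survive chrX/chrY + SNP filtering")
        universe = filtered.cpg_ids
        objects["filtered_beta"] = filtered
        done("filter", len(universe), [], removed=len(beta.cpg_ids) - len(universe))

        # -- differential methylation per contrast -------------------------
        current = "diffmeth"
        contrasts = [("d8", "d0", 1, "blast")]
        if len(sheet.samples(timepoint="d15", cycle=1, cell_type="blast")):
            contrasts.append(("d15", "d0", 1, "blast"))
        has_c2 = len(sheet.samples(cycle=2, cell_type="blast")) > 0
        if has_c2:
            contrasts.append(("d8", "d0", 2, "blast"))
        has_tcell = len(sheet.samples(cell_type="tcell")) > 0
        if has_tcell:
            contrasts.append(("d8", "d0", 1, "tcell"))
        diff_results = {}
        outputs = []
        for t1, t0, cyc, ct in contrasts:
            design = sheet.paired_design(t1, t0, cycle=cyc, cell_type=ct)
            res = PairedDifferentialModel(filtered, design).fit(
                alpha=config.alpha, delta_threshold=config.delta_threshold
            )
            diff_results[design.label()] = res
            path = out / f"diffmeth_{design.label()}.tsv"
            dio.write_result_table(
                res.table, path,
                {**params, "contrast": design.label(), "n_patients": design.n},
            )
            outputs.append(str(path))
        objects["diffmeth"] = diff_results
        blast_d8 = diff_results["blast_c1_d8_vs_d0"]
        done("diffmeth", sum(len(r.table) for r in diff_results.values()), outputs,
             contrasts=[lbl for lbl in diff_results])

        # -- kinetics ------------------------------------------------------
        current = "kinetics"
        d8_sets, omitted = single_sample_delta_sets(
            filtered, sheet, "d8", "d0", cycle=1, cell_type="blast",
            delta_threshold=config.delta_threshold,
        )
        scale = len(universe) / FULL_ARRAY_CPGS
        strong_thr = int(round(100_000 * scale))
        limited_thr = int(round(25_000 * scale))
        kin = pd.DataFrame(
            {
                "patient_id": sorted(d8_sets),
                "n_demethylated_d8": [len(d8_sets[p]) for p in sorted(d8_sets)],
                "magnitude": [
                    classify_demethylation_magnitude(
                        len(d8_sets[p]), strong_threshold=strong_thr,
                        limited_threshold=limited_thr,
                    )
                    for p in sorted(d8_sets)
                ],
            }
        ).set_index("patient_id")
        summary = cohort_methylation_summary(
            filtered, sheet, cell_type="blast", cycle=1,
            delta_threshold=config.delta_threshold,
        )
        kin_path = out / "kinetics.tsv"
        dio.write_result_table(
            kin, kin_path,
            {**params, "strong_threshold": strong_thr, "limited_threshold": limited_thr,
             **{f"median_beta_{tp}": round(v, 4) for tp, v in summary.median_beta.items()}},
        )
        objects["d8_sets"] = d8_sets
        objects["kinetics"] = kin
        objects["summary"] = summary
        done("kinetics", len(kin), [str(kin_path)], omitted_patients=omitted)

        # -- signature null ------------------------------------------------
        current = "signature_null"
        sig_model = SignatureNullModel(
            d8_sets, universe,
            groupwise_significant=blast_d8.demethylated_set(),
            min_fraction=config.min_fraction,
        )
        sig_res = sig_model.fit(
            n_iterations=config.n_iterations, seed=_stage_seed(config.seed, 1)
        )
        sig_table = pd.DataFrame(
            {"cpg_id": sorted(sig_res.signature_cpg_ids)}
        ).set_index("cpg_id")
        sig_path = out / "signature_cpgs.tsv"
        null_path = out / "signature_null_counts.tsv"
        dio.write_result_table(
            sig_table, sig_path,
            {**params, "observed": sig_res.observed_common_count,
             "null_mean": round(sig_res.null_mean, 3),
             "null_sd": round(sig_res.null_sd, 3), "p_tail": sig_res.p_tail},
        )
        dio.write_result_table(
            pd.DataFrame({"null_count": sig_res.null_counts}), null_path, params,
            index=False,
        )
        objects["signature"] = sig_res
        done("signature_null", sig_res.observed_common_count,
             [str(sig_path), str(null_path)], p_tail=sig_res.p_tail)

        # -- remethylation -------------------------------------------------
        current = "remethylation"
        if len(sheet.samples(timepoint="d15", cycle=1, cell_type="blast")):
            remeth = remethylation_analysis(
                filtered, sheet, d8_sets, blast_d8.demethylated_set(), universe,
                alpha=config.alpha, partial_delta=config.partial_delta,
                n_iterations=config.n_iterations, seed=_stage_seed(config.seed, 2),
            )
            rem_table = pd.DataFrame(
                {
                    "patient_id": sorted(remeth.per_patient_sets),
                    "n_d8": [len(d8_sets[p]) for p in sorted(remeth.per_patient_sets)],
                    "n_remethylated": [
                        len(remeth.per_patient_sets[p])
                        for p in sorted(remeth.per_patient_sets)
                    ],
                }
            ).set_index("patient_id")
            rem_path = out / "remethylation.tsv"
            dio.write_result_table(
                rem_table, rem_path,
                {**params,
                 "per_patient_fraction": round(remeth.per_patient_fraction, 4),
                 "group_fraction": round(remeth.group_fraction, 4)
                 if remeth.group_fraction == remeth.group_fraction else "nan",
                 "null_p_tail": remeth.null.p_tail},
            )
            objects["remethylation"] = remeth
            done("remethylation", len(rem_table), [str(rem_path)],
                 per_patient_fraction=remeth.per_patient_fraction,
                 null_p_tail=remeth.null.p_tail)
        else:
            skip("remethylation", "no day-15 samples")

        # -- cycle concordance ---------------------------------------------
        current = "cycle_concordance"
        if has_c2:
            c2_res = diff_results["blast_c2_d8_vs_d0"]
            c2_patients = sheet.patients(cell_type="blast", cycle=2)
            c2_sets, _ = single_sample_delta_sets(
                filtered, sheet, "d8", "d0", cycle=2, cell_type="blast",
                delta_threshold=config.delta_threshold,
            )
            # group-wise call sets of the two cycles, restricted to the
            # patients profiled in both
            c1_design = sheet.paired_design("d8", "d0", cycle=1, cell_type="blast",
                                            patients=c2_patients)
            c1_res_sub = PairedDifferentialModel(filtered, c1_design).fit(
                alpha=config.alpha, delta_threshold=config.delta_threshold
            )
            overlap = cycle_overlap(
                c1_res_sub.demethylated_set(), c2_res.demethylated_set()
            )
            recurrence = cycle_overlap(
                sig_res.signature_cpg_ids, c2_res.demethylated_set()
            )
            enrich = signature_enrichment_per_sample(
                sig_res.signature_cpg_ids, c2_sets, set(universe)
            ) if sig_res.signature_cpg_ids else {}
            cyc_table = pd.DataFrame(
                [
                    {
                        "patient_id": p,
                        "pct_universe_demethylated": round(e.pct_universe_called, 3),
                        "pct_signature_demethylated": round(e.pct_signature_called, 3),
                        "odds_ratio": e.odds_ratio,
                        "fisher_p": e.p,
                        "stars": e.stars,
                    }
                    for p, e in sorted(enrich.items())
                ]
            )
            if len(cyc_table):
                cyc_table = cyc_table.set_index("patient_id")
            cyc_path = out / "cycle_concordance.tsv"
            dio.write_result_table(
                cyc_table, cyc_path,
                {**params, "n_c1": overlap.n_first, "n_c2": overlap.n_second,
                 "n_overlap": overlap.n_common,
                 "signature_recurrence": round(recurrence.fraction_recurring, 4)
                 if recurrence.n_first else "nan"},
            )
            objects["cycle_overlap"] = overlap
            objects["signature_recurrence"] = recurrence
            objects["cycle_enrichment"] = enrich
            done("cycle_concordance", overlap.n_common, [str(cyc_path)],
                 signature_recurrence=recurrence.fraction_recurring)
        else:
            skip("cycle_concordance", "no cycle-2 samples")

        # -- T-cell contrast -----------------------------------------------
        current = "tcell_contrast"
        if has_tcell:
            t_sets, _ = single_sample_delta_sets(
                filtered, sheet, "d8", "d0", cycle=1, cell_type="tcell",
                delta_threshold=config.delta_threshold,
            )
            t_model = SignatureNullModel(
                t_sets, universe,
                groupwise_significant=diff_results["tcell_c1_d8_vs_d0"].demethylated_set(),
                min_fraction=config.min_fraction,
            )
            t_res = t_model.fit(
                n_iterations=config.n_iterations, seed=_stage_seed(config.seed, 3)
            )
            t_table = pd.DataFrame(
                {
                    "patient_id": sorted(t_sets),
                    "n_demethylated_d8": [len(t_sets[p]) for p in sorted(t_sets)],
                }
            ).set_index("patient_id")
            t_path = out / "tcell_contrast.tsv"
            dio.write_result_table(
                t_table, t_path,
                {**params, "common_count": t_res.observed_common_count,
                 "p_tail": t_res.p_tail,
                 "blast_common_count": sig_res.observed_common_count},
            )
            objects["tcell"] = t_res
            objects["tcell_sets"] = t_sets
            done("tcell_contrast", t_res.observed_common_count, [str(t_path)],
                 p_tail=t_res.p_tail)
        else:
            skip("tcell_contrast", "no T-cell samples")

        # -- responder screen ----------------------------------------------
        current = "responder_screen"
        groups = sheet.response_groups(cell_type="blast")
        labels = set(groups.values())
        if {"responder", "nonresponder"} <= labels:
            resp_set = responder_screen(
                d8_sets, groups, hi=config.responder_hi, lo=config.responder_lo
            )
            resp_table = pd.DataFrame({"cpg_id": sorted(resp_set)}).set_index("cpg_id") \
                if resp_set else pd.DataFrame(columns=["cpg_id"]).set_index("cpg_id")
            resp_path = out / "responder_screen.tsv"
            dio.write_result_table(resp_table, resp_path, params)
            objects["responder_screen"] = resp_set
            done("responder_screen", len(resp_set), [str(resp_path)])
        else:
            skip("responder_screen", "response groups not available")

        # -- expression integration ----------------------------------------
        current = "expression_integration"
        if expr is not None:
            expr_cols = set(expr.sample_ids)
            full_design = sheet.paired_design("d8", "d0", cycle=1, cell_type="blast")
            keep = [
                k for k, p in enumerate(full_design.patients)
                if full_design.t1_samples[k] in expr_cols
                and full_design.t0_samples[k] in expr_cols
            ]
            if len(keep) >= 5:
                from .datamodel import PairedDesign

                design = PairedDesign(
                    patients=tuple(full_design.patients[k] for k in keep),
                    t1_samples=tuple(full_design.t1_samples[k] for k in keep),
                    t0_samples=tuple(full_design.t0_samples[k] for k in keep),
                    t1="d8", t0="d0", cycle=1, cell_type="blast",
                )
                deg = paired_deg(expr, design, alpha=config.alpha)
                region = gene_region_beta(filtered, annot.for_cpgs(universe))
                screen = AntiCorrelationScreen(region, deg.log2fc, design).fit(
                    alpha=config.screen_alpha
                )
                scr_path = out / "anticorrelation_screen.tsv"
                dio.write_result_table(
                    screen.table, scr_path,
                    {**params, "n_patients": design.n,
                     "n_called_genes": len(screen.called_genes())},
                    index=False,
                )
                objects["deg"] = deg
                objects["screen"] = screen
                done("expression_integration", len(screen.table), [str(scr_path)],
                     n_called_genes=len(screen.called_genes()))
            else:
                skip("expression_integration",
                     "fewer than 5 patients with paired expression")
        else:
            skip("expression_integration", "no expression matrix")

        # -- context enrichment --------------------------------------------
        current = "context_enrichment"
        ctx = context_enrichment(sig_res.signature_cpg_ids, set(universe),
                                 annot.for_cpgs(universe))
        ctx_path = out / "context_enrichment.tsv"
        dio.write_result_table(ctx, ctx_path, params, index=False)
        objects["context"] = ctx
        done("context_enrichment", len(ctx), [str(ctx_path)])

    except Exception as exc:
        manifest["failed_stage"] = current
        dio.write_json(manifest, out / "manifest.json")
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc

    manifest["elapsed_s"] = round(time.perf_counter() - t_start, 2)
    dio.write_json(manifest, out / "manifest.json")
    return PipelineResult(manifest=manifest, objects=objects)
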