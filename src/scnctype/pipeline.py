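"""End-to-end pipeline orchestration.

Runs the stages in the order the analysis proceeds: normalization ->
NE scoring -> TF subtype assignment (with reclassification) ->
cell-state deconvolution -> pathway / NEv2 scoring -> outcome statistics.
Every run writes its artifacts plus a manifest (parameters and input
checksums) sufficient to reproduce it; with a ``simulate`` block the
inputs come from the synthetic cohort generator and a truth-vs-estimate
report is added.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import expr_io, signatures, deconvolution, subtyping, pathways, clinical
from .simulate import CohortSpec, SyntheticCohort, generate_cohort

logger = logging.getLogger("scnctype")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Input paths (or a simulate block), stage parameters, seed, outdir."""

    outdir: str = "scnctype_out"
    seed: int = 0
    simulate: dict | None = None  # CohortSpec kwargs; None = real inputs
    counts: str | None = None
    gene_lengths: str | None = None
    centroid: str | None = None
    pathways_gmt: str | None = None
    nev2_pathways: str | None = None  # text file, one pathway name per line
    signature_matrix: str | None = None
    clinical_csv: str | None = None
    variants_tsv: str | None = None
    ssgsea_alpha: float = 0.25
    n_clusters: int = 3
    n_top_pathways: int = 1000
    deconv_method: str = "nnls"
    n_permutations: int = 0  # permutation p per sample is opt-in (costly)

    def validate(self) -> None:
        if self.simulate is None:
            required = {
                "counts": self.counts,
                "gene_lengths": self.gene_lengths,
                "centroid": self.centroid,
                "pathways_gmt": self.pathways_gmt,
                "nev2_pathways": self.nev2_pathways,
                "signature_matrix": self.signature_matrix,
                "clinical_csv": self.clinical_csv,
            }
            missing = [k for k, v in required.items() if v is None]
            if missing:
                raise ValueError(f"missing required inputs: {missing}")


def load_config(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage(name, fn, timings):
    t0 = time.perf_counter()
    try:
        out = fn()
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    timings[name] = round(time.perf_counter() - t0, 3)
    logger.info("stage %s done in %.2fs", name, timings[name])
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the result bundle (also written to outdir)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict = {}
    report: dict = {"seed": config.seed}

    # ------------------------------------------------------------ inputs
    if config.simulate is not None:
        spec = CohortSpec(**{"seed": config.seed, **config.simulate})
        cohort = _stage("simulate", lambda: generate_cohort(spec), timings)
        counts = cohort.counts
        lengths = cohort.gene_lengths
        centroid = cohort.centroid
        collection = cohort.pathway_collection
        nev2_names = cohort.nev2_pathway_names
        sig_matrix = cohort.signature_matrix
        clin = cohort.clinical
        truth = cohort.truth
    else:
        counts = expr_io.read_counts(config.counts)
        lengths = expr_io.read_gene_lengths(config.gene_lengths)
        centroid = signatures.read_centroid_signature(config.centroid)
        collection = signatures.parse_gmt(config.pathways_gmt)
        nev2_names = [
            l.strip()
            for l in Path(config.nev2_pathways).read_text().splitlines()
            if l.strip()
        ]
        sig_matrix = deconvolution.read_signature_matrix(config.signature_matrix)
        clin = clinical.read_clinical(config.clinical_csv)
        truth = None

    # ------------------------------------------------------- normalize
    expr = _stage(
        "normalize", lambda: expr_io.tmm_fpkm_log2(counts, lengths), timings
    )
    edf = expr.to_frame()
    expr_io.write_matrix(edf, out / "normalized_expression.tsv")

    # ------------------------------------------------------- NE scoring
    ne = _stage("ne_score", lambda: signatures.ne_score(edf, centroid), timings)
    ne.to_frame().to_csv(out / "ne_scores.csv")
    report["n_ne"] = int(sum(l == "NE" for l in ne.labels))
    report["n_samples"] = len(ne.samples)

    repstress = signatures.weighted_zscore_score(
        edf, signatures.WeightedSignature.repstress()
    )
    repstress.rename("repstress").to_csv(out / "repstress_scores.csv")

    # ------------------------------------------- patient-level subtyping
    if truth is not None:
        sample_to_patient = dict(
            zip(truth.samples["sample"], truth.samples["patient"])
        )
    elif "patient" in clin.columns and len(clin) == len(edf.columns):
        sample_to_patient = dict(zip(edf.columns, clin["patient"]))
    else:
        sample_to_patient = {s: s for s in edf.columns}
    pat_expr = edf.T.groupby(
        edf.columns.map(sample_to_patient.get)
    ).mean().T  # genes x patients

    pat_ne = _stage(
        "ne_score_patient", lambda: signatures.ne_score(pat_expr, centroid), timings
    )
    tf_expr = pat_expr.loc[list(subtyping.CORE_TFS)]
    assignment = _stage(
        "subtype",
        lambda: subtyping.assign_subtypes(tf_expr, pat_ne, k=config.n_clusters),
        timings,
    )
    assignment.to_frame().to_csv(out / "subtypes.csv")
    report["subtype_counts"] = (
        pd.Series(assignment.labels).value_counts().to_dict()
    )
    report["n_reclassified"] = int(assignment.reclassified.sum())

    agree = subtyping.agreement_kappa(
        assignment.ne_category_of_label, list(pat_ne.labels)
    )
    report["tf_vs_ne_percent_agreement"] = round(agree.percent_agreement, 2)
    report["tf_vs_ne_kappa"] = round(agree.kappa, 4)

    # ------------------------------------------------------ deconvolution
    params = deconvolution.DeconvolutionParams(
        method=config.deconv_method, n_permutations=config.n_permutations
    )
    fractions = _stage(
        "deconvolve",
        lambda: deconvolution.estimate_fractions(
            edf, sig_matrix, params, seed=config.seed
        ),
        timings,
    )
    fractions.to_frame().to_csv(out / "fractions.tsv", sep="\t", index=False)

    # -------------------------------------------------- pathways / NEv2
    ssp = signatures.SsgseaParams(alpha=config.ssgsea_alpha)
    pscores = _stage(
        "pathway_scores",
        lambda: pathways.score_pathway_collection(edf, collection, ssp),
        timings,
    )
    expr_io.write_matrix(pscores, out / "pathway_scores.tsv", index_label="pathway")

    sample_ne_labels = pd.Series(ne.labels, index=ne.samples)
    diff = _stage(
        "differential_pathways",
        lambda: pathways.differential_pathways(
            pscores, sample_ne_labels,
            n_top=min(config.n_top_pathways, pscores.shape[0]),
        ),
        timings,
    )
    diff.to_csv(out / "differential_pathways.csv")
    (out / "selected_pathways.txt").write_text(
        "\n".join(diff.index[diff["selected"]]) + "\n"
    )

    nev2 = _stage(
        "nev2",
        lambda: pathways.nev2_score_and_label(pscores, nev2_names),
        timings,
    )
    nev2.to_frame().to_csv(out / "nev2.csv")
    report["n_nev2_like"] = int(nev2.nev2_like.sum())

    # ---------------------------------------------------------- outcomes
    outcome_stats: dict = {}
    if clin is not None and len(clin) > 0:
        pat_nev2 = (
            pd.DataFrame(
                {"sample": nev2.samples, "nev2": nev2.nev2_like}
            )
            .assign(patient=lambda d: d["sample"].map(sample_to_patient.get))
            .groupby("patient")["nev2"].any()
        )
        clin2 = clin.assign(
            nev2=clin["patient"].map(pat_nev2).fillna(False).astype(bool)
        )
        if clin2["nev2"].nunique() == 2 and clin2["os_event"].sum() > 0:
            try:
                comp = clinical.compare_survival(clin2, "nev2", "os")
                outcome_stats["nev2_os"] = {
                    "median_other": comp.medians.get(False),
                    "median_nev2": comp.medians.get(True),
                    "hr": round(comp.hazard_ratio, 3),
                    "ci": [round(comp.ci_low, 3), round(comp.ci_high, 3)],
                    "logrank_p": round(comp.logrank_p, 5),
                }
            except ValueError as exc:
                logger.warning("NEv2 survival comparison skipped: %s", exc)
        benefit = clinical.clinical_benefit(clin2, group_col="arm")
        outcome_stats["clinical_benefit_by_arm"] = {
            k: round(float(v), 4) for k, v in benefit.items()
        }
    report["outcomes"] = outcome_stats

    # ------------------------------------------------ truth-vs-estimate
    if truth is not None:
        st = truth.samples.set_index("sample")
        ne_pred = pd.Series(ne.labels, index=ne.samples)
        report["recovery"] = recov = {}
        recov["ne_accuracy"] = float((ne_pred == st["ne_label"]).mean())

        sub_pred = pd.Series(assignment.labels, index=assignment.patients)
        pt = truth.patients.set_index("patient")
        recov["subtype_accuracy"] = float(
            (sub_pred == pt["subtype"].loc[sub_pred.index]).mean()
        )

        nev2_pred = pd.Series(nev2.nev2_like, index=nev2.samples)
        truth_flag = st["nev2"].astype(bool)
        tp = int((nev2_pred & truth_flag).sum())
        fn = int((~nev2_pred & truth_flag).sum())
        tn = int((~nev2_pred & ~truth_flag).sum())
        fp = int((nev2_pred & ~truth_flag).sum())
        recov["nev2_sensitivity"] = tp / (tp + fn) if (tp + fn) else float("nan")
        recov["nev2_specificity"] = tn / (tn + fp) if (tn + fp) else float("nan")

        ne_frac_est = fractions.wide()["NE"]
        rho = spearmanr(ne_frac_est, st["ne_fraction"].loc[ne_frac_est.index])[0]
        recov["ne_fraction_rank_corr"] = float(rho)

    # ------------------------------------------------------- manifest
    manifest = {
        "config": asdict(config),
        "timings_s": timings,
        "input_checksums": {},
    }
    for key in (
        "counts", "gene_lengths", "centroid", "pathways_gmt",
        "nev2_pathways", "signature_matrix", "clinical_csv", "variants_tsv",
    ):
        p = getattr(config, key)
        if p is not None and Path(p).exists():
            manifest["input_checksums"][key] = _checksum(Path(p))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
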