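"""End-to-end study orchestration: simulate, partition, train, calibrate,
deconvolute, evaluate and run the DQ analytics in one call.

This is the module the CLI, the examples and the acceptance script drive; each
step is an ordinary call into the underlying modules, so everything here can
also be composed by hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import deconvolution, dq, evaluation
from .calibration import build_calibrations
from .datasets import partition_common_motif
from .nnalign import EnsembleModel, TrainingConfig, train
from .synthetic import StudyBundle, StudyConfig, generate_study


@dataclass
class StudyResults:
    bundle: StudyBundle
    model: EnsembleModel
    annotations: pd.DataFrame
    metrics: pd.DataFrame
    motif_recovery: pd.DataFrame
    contribution: pd.DataFrame
    coverage: pd.DataFrame
    newick: str
    summary: dict = field(default_factory=dict)


def annotate_cv(model: EnsembleModel, bundle: StudyBundle, partitioning) -> pd.DataFrame:
    """Concatenated cross-validation annotations for every EL record: each
    peptide is scored only by ensemble members that held its fold out."""
    frames = []
    for sid, sample in bundle.samples.items():
        recs = bundle.el[bundle.el["sample_id"] == sid]
        folds = np.array([partitioning.assignment[p] for p in recs["peptide"]])
        ann = deconvolution.assign_restriction(
            model,
            sample,
            recs["peptide"].tolist(),
            targets=recs["target"].to_numpy(),
            peptide_folds=folds,
        )
        frames.append(ann)
    return pd.concat(frames, ignore_index=True)


def motif_recovery(annotations: pd.DataFrame, bundle: StudyBundle) -> pd.DataFrame:
    """Correlation between each planted motif and the PSSM recovered from the
    non-trash positives deconvoluted to that molecule."""
    df = annotations[(~annotations["is_trash"]) & (annotations["target"] == 1)]
    rows = []
    for name, motif in bundle.motifs.items():
        sub = df[df["molecule"] == name]
        if len(sub) >= deconvolution.MIN_PSSM_PEPTIDES:
            pssm = deconvolution.build_pssm(deconvolution.cores_from_annotations(sub))
            pcc = float(
                np.corrcoef(motif.matrix.reshape(-1), pssm.freq.reshape(-1))[0, 1]
            )
        else:
            pcc = float("nan")
        rows.append({"molecule": name, "n_peptides": len(sub), "pcc": pcc})
    return pd.DataFrame(rows)


def ma_assignment_accuracy(annotations: pd.DataFrame, bundle: StudyBundle) -> float:
    """Fraction of MA-sample positives (with a generating molecule) assigned to
    that molecule by the trained model."""
    ma_ids = [s.sample_id for s in bundle.samples.values() if s.kind == "MA"]
    truth = bundle.truth[
        bundle.truth["sample_id"].isin(ma_ids) & (bundle.truth["molecule"] != "trash")
    ].drop_duplicates(["sample_id", "peptide"])
    ann = annotations[annotations["target"] == 1].drop_duplicates(["sample_id", "peptide"])
    merged = truth.merge(ann, on=["sample_id", "peptide"], suffixes=("_true", "_pred"))
    if merged.empty:
        return float("nan")
    return float((merged["molecule_true"] == merged["molecule_pred"]).mean())


def trans_only_fraction(annotations: pd.DataFrame, bundle: StudyBundle) -> float:
    """Fraction of non-trash DQ annotations in heterozygous samples that went
    to trans-only molecules."""
    ma_ids = [s.sample_id for s in bundle.samples.values() if s.kind == "MA"]
    df = annotations[
        annotations["sample_id"].isin(ma_ids)
        & (annotations["target"] == 1)
        & (~annotations["is_trash"])
    ]
    if df.empty:
        return float("nan")
    is_trans = df["molecule"].map(lambda m: dq.classify_molecule(m) == "trans_only")
    return float(is_trans.mean())


def run_study(
    study_config: StudyConfig | None = None,
    training_config: TrainingConfig | None = None,
    seed: int = 0,
    calibration_n: int = 10000,
    tree_n: int = 5000,
    hook=None,
) -> StudyResults:
    """Generate a synthetic study, train the ensemble with 5-fold common-motif
    cross-validation, and compute the full analytic read-out."""
    study_config = study_config or StudyConfig(seed=seed)
    training_config = training_config or TrainingConfig.desk(seed=seed)
    bundle = generate_study(study_config)

    all_peptides = pd.concat([bundle.el["peptide"], bundle.ba["peptide"]], ignore_index=True)
    partitioning = partition_common_motif(all_peptides, k=training_config.n_folds, seed=seed)

    model = train(
        bundle.el,
        bundle.ba,
        bundle.samples,
        partitioning,
        bundle.pseudo_table,
        config=training_config,
        hook=hook,
    )

    all_molecules = sorted({m for s in bundle.samples.values() for m in s.molecules})
    model.calibrations.update(
        build_calibrations(
            model, all_molecules, bundle.proteome, n=calibration_n, seed=seed
        )
    )

    annotations = annotate_cv(model, bundle, partitioning)
    metrics = evaluation.evaluate_cv(annotations)
    recovery = motif_recovery(annotations, bundle)
    contribution = dq.contribution_analysis(
        annotations[annotations["target"] == 1],
        bundle.samples,
        sa_molecules=bundle.sa_molecules,
    )
    cov = dq.coverage(annotations)
    cov_ext = dq.extended_coverage(cov, dict(bundle.pseudo_table.entries))
    dist = dq.specificity_distance(
        model, sorted(bundle.pseudo_table.names()), bundle.proteome, n=tree_n, seed=seed
    )
    newick = dq.build_tree(dist)

    cat = dq.category_means(contribution)
    summary = {
        "n_el_records": int(len(bundle.el)),
        "n_positives": int((bundle.el["target"] == 1).sum()),
        "n_negatives": int((bundle.el["target"] == 0).sum()),
        "n_molecules_evaluated": int(len(metrics)),
        "cv_mean_auc": float(metrics["auc"].mean()),
        "cv_min_auc": float(metrics["auc"].min()),
        "cv_mean_auc01": float(metrics["auc01"].mean()),
        "cv_mean_ppv": float(metrics["ppv"].mean()),
        "ma_assignment_accuracy": ma_assignment_accuracy(annotations, bundle),
        "motif_recovery_mean_pcc": float(recovery["pcc"].mean()),
        "motif_recovery_min_pcc": float(recovery["pcc"].min()),
        "trans_only_fraction": trans_only_fraction(annotations, bundle),
        "trans_only_mean_contribution": cat["trans_only"],
        "cis_sa_mean_contribution": cat["cis_SA"],
        "cis_ma_mean_contribution": cat["cis_MA"],
        "n_covered_molecules": int(cov["covered"].sum()),
        "n_extended_covered_molecules": int(cov_ext["extended_covered"].sum()),
    }
    return StudyResults(
        bundle=bundle,
        model=model,
        annotations=annotations,
        metrics=metrics,
        motif_recovery=recovery,
        contribution=contribution,
        coverage=cov_ext,
        newick=newick,
        summary=summary,
    )
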