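"""Restriction assignment, trash filtering, motif PSSMs and consistency analysis.

After training, every peptide of a multi-allelic sample is assigned to the
expressed molecule giving it the highest prediction score.  Assignments whose
percentile rank exceeds 20 are flagged *trash* — MS contaminants that no
expressed molecule explains — and excluded from motif-level analyses.  Motifs
are summarized as 9-position position-specific scoring matrices (PSSMs) over
the predicted binding cores; motif consistency of a molecule is the mean
Pearson correlation of its PSSMs between pairs of cell lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .blosum import AMINO_ACIDS, seq_to_indices
from .calibration import percentile_rank

TRASH_RANK = 20.0
MIN_PSSM_PEPTIDES = 20
PSSM_PSEUDOCOUNT = 0.05  # Laplace 1/20 per cell


def assign_restriction(
    ensemble,
    sample,
    peptides,
    targets=None,
    peptide_folds=None,
    calibrations: dict | None = None,
    trash_rank: float = TRASH_RANK,
    annotate_by: str = "score",
) -> pd.DataFrame:
    """Annotate each peptide of a sample with its restricting molecule.

    The winner is the sample molecule with the highest raw ensemble score
    (``annotate_by="rank"`` instead picks the lowest percentile rank, the
    convention used for cross-method benchmarks); ties break lexicographically
    by molecule name.  The percentile rank of the winning molecule defines the
    trash flag (rank > ``trash_rank``).  Requires a calibration for every
    sample molecule.
    """
    peptides = list(peptides)
    calibrations = calibrations if calibrations is not None else ensemble.calibrations
    molecules = sorted(sample.molecules)
    for m in molecules:
        if m not in calibrations:
            raise KeyError(f"missing percentile-rank calibration for molecule {m}")
    scores, offsets = ensemble.score_matrix(
        peptides, molecules, peptide_folds=peptide_folds, return_offsets=True
    )
    ranks = np.column_stack(
        [percentile_rank(scores[:, j], calibrations[m]) for j, m in enumerate(molecules)]
    )
    if annotate_by == "score":
        win = scores.argmax(axis=1)
    elif annotate_by == "rank":
        win = ranks.argmin(axis=1)
    else:
        raise ValueError("annotate_by must be 'score' or 'rank'")
    rows = np.arange(len(peptides))
    out = pd.DataFrame(
        {
            "peptide": peptides,
            "sample_id": sample.sample_id,
            "molecule": [molecules[w] for w in win],
            "score": scores[rows, win],
            "rank": ranks[rows, win],
            "core_offset": offsets[rows, win],
            "is_trash": ranks[rows, win] > trash_rank,
        }
    )
    if targets is not None:
        out["target"] = np.asarray(targets, dtype=np.float64)
    return out


def write_annotations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def union_nontrash(ann_a: pd.DataFrame, ann_b: pd.DataFrame):
    """Restrict two models' annotations of the same data to peptides that are
    non-trash in *both* — the filter applied before comparing motif
    consistency between models, so contaminants flagged by either model cannot
    bias the comparison."""
    trash_keys = set()
    for ann in (ann_a, ann_b):
        t = ann.loc[ann["is_trash"], ["sample_id", "peptide"]]
        trash_keys |= set(map(tuple, t.itertuples(index=False)))

    def keep(ann):
        keys = list(zip(ann["sample_id"], ann["peptide"]))
        mask = [k not in trash_keys for k in keys]
        return ann[mask].reset_index(drop=True)

    return keep(ann_a), keep(ann_b)


# ---------------------------------------------------------------------------
# PSSMs


@dataclass
class Pssm:
    """Position-specific scoring matrix over a 9-mer core.

    ``freq`` has shape (9, 20): rows are core positions P1..P9, columns the
    residues in ``ACDEFGHIKLMNPQRSTVWY`` order; each row sums to 1.
    ``log_odds`` is log2(freq / background).
    """

    freq: np.ndarray
    log_odds: np.ndarray
    n_peptides: int
    background: np.ndarray = field(default_factory=lambda: np.full(20, 0.05))

    def information_content(self) -> np.ndarray:
        """Shannon information (bits) per core position, log2(20) - H."""
        f = self.freq
        h = -np.sum(np.where(f > 0, f * np.log2(f), 0.0), axis=1)
        return np.log2(20.0) - h

    def flat(self) -> np.ndarray:
        return self.freq.reshape(-1)

    def write(self, path) -> None:
        df = pd.DataFrame(self.freq, columns=list(AMINO_ACIDS))
        df.insert(0, "pos", np.arange(1, self.freq.shape[0] + 1))
        df.to_csv(path, sep="\t", index=False)


def build_pssm(
    cores,
    background: np.ndarray | None = None,
    pseudocount: float = PSSM_PSEUDOCOUNT,
    min_peptides: int = MIN_PSSM_PEPTIDES,
) -> Pssm:
    """Frequency/log-odds PSSM from 9-mer binding cores.

    Refuses to build from fewer than ``min_peptides`` cores (too noisy to
    represent a motif).
    """
    cores = list(cores)
    if len(cores) < min_peptides:
        raise ValueError(f"need at least {min_peptides} cores to build a PSSM, got {len(cores)}")
    idx = np.stack([seq_to_indices(c) for c in cores])
    if idx.shape[1] != 9:
        raise ValueError("cores must be 9-mers")
    counts = np.zeros((9, 20), dtype=np.float64)
    for p in range(9):
        counts[p] = np.bincount(idx[:, p], minlength=20)
    freq = (counts + pseudocount) / (len(cores) + 20 * pseudocount)
    bg = np.asarray(background, dtype=np.float64) if background is not None else np.full(20, 0.05)
    log_odds = np.log2(freq / bg)
    return Pssm(freq=freq, log_odds=log_odds, n_peptides=len(cores), background=bg)


def cores_from_annotations(annotations: pd.DataFrame) -> list[str]:
    return [
        p[o : o + 9] for p, o in zip(annotations["peptide"], annotations["core_offset"])
    ]


def sample_pssms(
    annotations: pd.DataFrame,
    min_peptides: int = MIN_PSSM_PEPTIDES,
    positives_only: bool = True,
) -> dict[tuple[str, str], Pssm]:
    """PSSMs per (molecule, cell line) from non-trash positive annotations."""
    df = annotations[~annotations["is_trash"]]
    if positives_only and "target" in df:
        df = df[df["target"] == 1]
    out: dict[tuple[str, str], Pssm] = {}
    for (mol, sid), grp in df.groupby(["molecule", "sample_id"]):
        if len(grp) >= min_peptides:
            out[(mol, sid)] = build_pssm(cores_from_annotations(grp), min_peptides=min_peptides)
    return out


def pssm_correlation(a: Pssm, b: Pssm, use: str = "freq") -> float:
    """Pearson correlation of two flattened 180-value PSSMs."""
    va = (a.freq if use == "freq" else a.log_odds).reshape(-1)
    vb = (b.freq if use == "freq" else b.log_odds).reshape(-1)
    return float(np.corrcoef(va, vb)[0, 1])


def consistency(
    pssms: dict[tuple[str, str], Pssm], molecule: str, use: str = "freq"
) -> float | None:
    """Mean motif-consistency of one molecule across cell lines.

    The mean PCC between the molecule's PSSMs over every unique cell-line pair
    (self-pairs excluded); None when fewer than two cell lines qualify.  Trash
    removal (as the union over the compared models) happens upstream, before
    the PSSMs are built.
    """
    mats = [p for (mol, _), p in sorted(pssms.items()) if mol == molecule]
    if len(mats) < 2:
        return None
    ccs = [pssm_correlation(a, b, use=use) for a, b in combinations(mats, 2)]
    return float(np.mean(ccs))


def consistency_table(pssms: dict[tuple[str, str], Pssm], use: str = "freq") -> pd.Series:
    molecules = sorted({mol for mol, _ in pssms})
    return pd.Series(
        {m: consistency(pssms, m, use=use) for m in molecules}, name="consistency"
    )


# ---------------------------------------------------------------------------
# length summaries


def length_summary(
    annotations: pd.DataFrame, lengths: tuple[int, int] = (12, 21)
) -> pd.DataFrame:
    """Per-molecule peptide-length medians and histograms over non-trash
    positive annotations; molecules without peptides are omitted."""
    df = annotations[~annotations["is_trash"]]
    if "target" in df:
        df = df[df["target"] == 1]
    rows = []
    lo, hi = lengths
    for mol, grp in df.groupby("molecule"):
        lens = grp["peptide"].str.len()
        if lens.empty:
            continue
        hist = {L: int((lens == L).sum()) for L in range(lo, hi + 1)}
        rows.append({"molecule": mol, "n": len(lens), "median_length": float(lens.median()), **hist})
    return pd.DataFrame(rows)


def locus_length_means(summary: pd.DataFrame) -> pd.Series:
    """Mean of per-molecule median lengths grouped by locus."""
    from .hla import locus_of

    s = summary.copy()
    s["locus"] = s["molecule"].map(locus_of)
    return s.groupby("locus")["median_length"].mean()
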