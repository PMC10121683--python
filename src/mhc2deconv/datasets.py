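"""Peptide dataset IO, context mapping, random-negative enrichment and
common-motif cross-validation partitioning.

Eluted-ligand (EL) records are MS-identified peptides (length 12-21) labelled 1,
enriched per sample with random natural peptides labelled 0.  Binding-affinity
(BA) records carry a log-transformed IC50 in [0, 1].  Cross-validation folds are
built with the common-motif rule: peptides sharing an identical run of 9 or more
residues always land in the same fold, so no motif information leaks between
training and test folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .blosum import AMINO_ACIDS, is_standard

EL_LENGTH_RANGE = (12, 21)
CONTEXT_LENGTH = 12
CONTEXT_PAD = "A"
NEGATIVE_MULTIPLIER = 5
AFFINITY_MAX_NM = 50000.0


@dataclass(frozen=True)
class PeptideRecord:
    sequence: str
    target: float
    assay: str  # "EL" or "BA"
    sample_id: str
    context: str | None = None
    molecule: str | None = None  # BA records are per-molecule

    def __post_init__(self):
        if self.assay not in ("EL", "BA"):
            raise ValueError(f"assay must be EL or BA, got {self.assay!r}")
        if not 0.0 <= self.target <= 1.0:
            raise ValueError(f"target {self.target} outside [0, 1]")
        if self.assay == "EL" and self.target not in (0.0, 1.0):
            raise ValueError(f"EL target must be 0 or 1, got {self.target}")


@dataclass(frozen=True)
class Sample:
    """A cell line / donor sample and the molecules it expresses."""

    sample_id: str
    molecules: tuple[str, ...]

    def __post_init__(self):
        if not self.molecules:
            raise ValueError(f"sample {self.sample_id}: empty molecule list")
        object.__setattr__(self, "molecules", tuple(self.molecules))

    @property
    def kind(self) -> str:
        return "SA" if len(self.molecules) == 1 else "MA"


# ---------------------------------------------------------------------------
# readers / writers


def read_peptide_tsv(path) -> pd.DataFrame:
    """Read ``peptide<TAB>target<TAB>sample_id[<TAB>context]`` into a DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] not in (3, 4):
        raise ValueError(f"{path}: expected 3 or 4 tab-separated columns, got {df.shape[1]}")
    df.columns = ["peptide", "target", "sample_id", "context"][: df.shape[1]]
    df["target"] = df["target"].astype(float)
    return df


def write_peptide_tsv(df: pd.DataFrame, path) -> None:
    cols = ["peptide", "target", "sample_id"] + (["context"] if "context" in df else [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_sample_map(path) -> dict[str, Sample]:
    """Read ``sample_id<TAB>comma-separated molecule names``."""
    samples: dict[str, Sample] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            sid, mols = fields
            samples[sid] = Sample(sid, tuple(m.strip() for m in mols.split(",") if m.strip()))
    return samples


def write_sample_map(samples: dict[str, Sample], path) -> None:
    with open(path, "w") as fh:
        for s in samples.values():
            fh.write(f"{s.sample_id}\t{','.join(s.molecules)}\n")


def read_proteome(path) -> dict[str, str]:
    """Read a FASTA proteome into ``{accession: sequence}``."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_proteome(proteome: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in proteome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def filter_length(df: pd.DataFrame, lengths: tuple[int, int] = EL_LENGTH_RANGE) -> pd.DataFrame:
    """Keep peptides within the class II ligand length window (default 12-21)."""
    lens = df["peptide"].str.len()
    return df[(lens >= lengths[0]) & (lens <= lengths[1])].reset_index(drop=True)


# ---------------------------------------------------------------------------
# context mapping


def map_context(peptide: str, proteome: dict[str, str]) -> str | None:
    """Source-protein context of a peptide: 3 upstream + first 3 + last 3 + 3 downstream.

    The peptide must occur verbatim in the proteome; residues beyond the protein
    ends are padded with ``A``.  Returns ``None`` (record to be discarded) when
    the peptide has no identical match.  Among multiple occurrences the
    lexicographically smallest (accession, offset) is used, so the result is
    deterministic.
    """
    if not proteome:
        raise ValueError("empty proteome")
    best: tuple[str, int] | None = None
    for acc in sorted(proteome):
        pos = proteome[acc].find(peptide)
        if pos >= 0:
            best = (acc, pos)
            break
    if best is None:
        return None
    acc, pos = best
    prot = proteome[acc]
    up = prot[max(0, pos - 3) : pos].rjust(3, CONTEXT_PAD)
    down = prot[pos + len(peptide) : pos + len(peptide) + 3].ljust(3, CONTEXT_PAD)
    return up + peptide[:3] + peptide[-3:] + down


def add_context(df: pd.DataFrame, proteome: dict[str, str]) -> pd.DataFrame:
    """Map contexts for all positives; peptides without a proteome match are dropped."""
    contexts = df["peptide"].map(lambda p: map_context(p, proteome))
    out = df.copy()
    out["context"] = contexts
    return out[out["context"].notna()].reset_index(drop=True)


# ---------------------------------------------------------------------------
# random natural peptides / negative enrichment


def sample_natural_peptides(
    proteome: dict[str, str],
    n: int,
    lengths: tuple[int, int],
    rng: np.random.Generator,
) -> list[str]:
    """Draw n random subsequences uniformly over lengths and over all possible
    start positions in the proteome."""
    accs = sorted(proteome)
    seqs = [proteome[a] for a in accs]
    lo, hi = lengths
    out: list[str] = []
    all_lengths = rng.integers(lo, hi + 1, size=n)
    for L in range(lo, hi + 1):
        count = int(np.sum(all_lengths == L))
        if count == 0:
            continue
        weights = np.array([max(0, len(s) - L + 1) for s in seqs], dtype=np.float64)
        if weights.sum() <= 0:
            raise ValueError(f"proteome has no subsequence of length {L}")
        probs = weights / weights.sum()
        idx = rng.choice(len(seqs), size=count, p=probs)
        for i in idx:
            start = int(rng.integers(0, len(seqs[i]) - L + 1))
            out.append(seqs[i][start : start + L])
    return out


def enrich_negatives(
    positives: pd.DataFrame,
    proteome: dict[str, str],
    multiplier: int = NEGATIVE_MULTIPLIER,
    lengths: tuple[int, int] = EL_LENGTH_RANGE,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Random natural negatives for one sample's positive EL peptides.

    Let M be the peptide count of the most prevalent length in the positives.
    For *each* length L in the window, ``multiplier * M`` random natural
    subsequences of length L are drawn uniformly from the proteome and labelled
    0 — with the default window and multiplier this is exactly 50 x M negatives.
    Draws colliding with a positive sequence are re-drawn (at most 100 retries)
    so labels stay consistent.
    """
    if positives.empty:
        raise ValueError("cannot enrich an empty positive set (no modal length)")
    if not proteome:
        raise ValueError("empty proteome")
    sample_ids = positives["sample_id"].unique()
    if len(sample_ids) != 1:
        raise ValueError("enrich_negatives operates on a single sample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    modal = int(positives["peptide"].str.len().value_counts().max())
    pos_set = set(positives["peptide"])
    lo, hi = lengths
    records: list[str] = []
    for L in range(lo, hi + 1):
        need = multiplier * modal
        drawn: list[str] = []
        retries = 0
        while len(drawn) < need:
            batch = sample_natural_peptides(proteome, need - len(drawn), (L, L), rng)
            fresh = [p for p in batch if p not in pos_set]
            if len(fresh) < len(batch):
                retries += 1
                if retries > 100:
                    raise RuntimeError("could not draw negatives distinct from positives")
            drawn.extend(fresh)
        records.extend(drawn[:need])
    return pd.DataFrame(
        {"peptide": records, "target": 0.0, "sample_id": sample_ids[0]}
    )


# ---------------------------------------------------------------------------
# common-motif partitioning


@dataclass
class Partitioning:
    """Peptide -> fold assignment respecting the shared-9-mer rule."""

    assignment: dict[str, int]
    n_folds: int = 5
    fold_sizes: list[int] = field(default_factory=list)

    def __getitem__(self, peptide: str) -> int:
        return self.assignment[peptide]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for pep, fold in self.assignment.items():
                fh.write(f"{pep}\t{fold}\n")

    @classmethod
    def read(cls, path, n_folds: int = 5) -> "Partitioning":
        assignment = {}
        with open(path) as fh:
            for line in fh:
                pep, fold = line.split()
                assignment[pep] = int(fold)
        return cls(assignment, n_folds=n_folds)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def partition_common_motif(
    peptides, k: int = 5, motif_length: int = 9, seed: int = 0
) -> Partitioning:
    """Partition peptides into k folds with the common-motif rule.

    Peptides sharing any identical ``motif_length``-mer are linked; connected
    components are atomic and distributed greedily (largest first, into the
    currently smallest fold, ties by fold index) to balance fold sizes.  The
    seed shuffles the initial peptide order so equal-size tie-breaks are
    reproducible but not order-dependent.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    peptides = list(dict.fromkeys(peptides))  # unique, keep first occurrence
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(peptides))
    peptides = [peptides[i] for i in order]

    parent = list(range(len(peptides)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    seen: dict[str, int] = {}
    for idx, pep in enumerate(peptides):
        for km in _kmers(pep, motif_length):
            if km in seen:
                union(idx, seen[km])
            else:
                seen[km] = idx

    components: dict[int, list[int]] = {}
    for idx in range(len(peptides)):
        components.setdefault(find(idx), []).append(idx)

    comps = sorted(components.values(), key=lambda c: (-len(c), min(c)))
    fold_sizes = [0] * k
    assignment: dict[str, int] = {}
    for comp in comps:
        fold = int(np.argmin(fold_sizes))
        for idx in comp:
            assignment[peptides[idx]] = fold
        fold_sizes[fold] += len(comp)
    return Partitioning(assignment, n_folds=k, fold_sizes=fold_sizes)


# ---------------------------------------------------------------------------
# binding-affinity transform


def transform_affinity(ic50_nm: float, max_nm: float = AFFINITY_MAX_NM) -> float:
    """Map an IC50 in nM to the [0, 1] training target: 1 - log(IC50)/log(50000)."""
    if ic50_nm <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nm}")
    return float(min(1.0, max(0.0, 1.0 - math.log(ic50_nm) / math.log(max_nm))))


def records_from_frames(
    el: pd.DataFrame, ba: pd.DataFrame | None = None
) -> list[PeptideRecord]:
    """Materialize PeptideRecord objects from EL and BA frames (BA frame columns:
    peptide, target, molecule)."""
    records = [
        PeptideRecord(
            sequence=r.peptide,
            target=float(r.target),
            assay="EL",
            sample_id=str(r.sample_id),
            context=getattr(r, "context", None),
        )
        for r in el.itertuples()
    ]
    if ba is not None:
        for r in ba.itertuples():
            records.append(
                PeptideRecord(
                    sequence=r.peptide,
                    target=float(r.target),
                    assay="BA",
                    sample_id=getattr(r, "sample_id", "BA"),
                    molecule=r.molecule,
                )
            )
    return records


def validate_sequences(df: pd.DataFrame) -> None:
    bad = [p for p in df["peptide"] if not is_standard(p)]
    if bad:
        raise ValueError(f"{len(bad)} peptides with non-standard residues, e.g. {bad[0]!r}")


__all__ = [
    "PeptideRecord",
    "Sample",
    "Partitioning",
    "read_peptide_tsv",
    "write_peptide_tsv",
    "read_sample_map",
    "write_sample_map",
    "read_proteome",
    "write_proteome",
    "filter_length",
    "map_context",
    "add_context",
    "sample_natural_peptides",
    "enrich_negatives",
    "partition_common_motif",
    "transform_affinity",
    "AMINO_ACIDS",
]
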