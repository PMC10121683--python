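"""HLA-DQ-specific analytics: cis/trans-only pairing, pseudo-sequence distance,
prevalent-molecule enumeration, coverage, contribution analysis and specificity
trees.

HLA-DQ heterodimers only assemble stably for certain alpha/beta combinations.
Combinations observed as haplotypes in population sequencing (DQA1*01 with
DQB1*05/06; DQA1*02-06 with DQB1*02/03/04, at two-digit resolution) are *cis*;
any pairing never observed as cis-encoded is *trans-only* and is believed not
to form a functional molecule.  The analytics here quantify how much of a
deconvoluted DQ immunopeptidome is attributed to trans-only variants, how well
the specificity space is covered, and how molecules cluster by predicted
specificity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .blosum import BLOSUM50, seq_to_indices
from .datasets import sample_natural_peptides
from .deconvolution import Pssm, build_pssm
from .hla import normalize_name

COVERAGE_MIN_FRACTION = 0.05
COVERAGE_MIN_TOTAL = 100
EXTENDED_COVERAGE_CUTOFF = 0.025
PREVALENCE_THRESHOLD = 0.00005
POPULATION_CAP = 1000
POPULATION_MIN_SIZE = 100

#: Observed two-digit DQA1-DQB1 haplotype groups (cis-encoded pairings).
DEFAULT_PAIRING_RULES: frozenset[tuple[str, str]] = frozenset(
    [("01", "05"), ("01", "06")]
    + [(a, b) for a in ("02", "03", "04", "05", "06") for b in ("02", "03", "04")]
)


@dataclass(frozen=True)
class PairingRuleTable:
    """Allowed (DQA1 group, DQB1 group) two-digit pairings."""

    pairs: frozenset[tuple[str, str]] = DEFAULT_PAIRING_RULES

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self.pairs

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for a, b in sorted(self.pairs):
                fh.write(f"DQA1*{a}\tDQB1*{b}\n")

    @classmethod
    def read(cls, path) -> "PairingRuleTable":
        pairs = set()
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                a, b = line.split()
                pairs.add((_group(a, "DQA1"), _group(b, "DQB1")))
        return cls(frozenset(pairs))


def _group(allele: str, gene: str) -> str:
    """Two-digit allele group of a DQA1/DQB1 allele name in any common style."""
    s = normalize_name(allele)
    m = re.fullmatch(rf"{gene}(\d{{2}})\d*", s)
    if not m:
        raise ValueError(f"cannot parse {gene} allele from {allele!r}")
    return m.group(1)


def classify_pairing(dqa: str, dqb: str, rules: PairingRuleTable | None = None) -> str:
    """Classify a DQ alpha/beta pairing as ``cis`` or ``trans_only``."""
    rules = rules or PairingRuleTable()
    return "cis" if (_group(dqa, "DQA1"), _group(dqb, "DQB1")) in rules else "trans_only"


def classify_molecule(name: str, rules: PairingRuleTable | None = None) -> str:
    """Classify a combined DQ molecule name (``DQA1xxxx-DQB1yyyy``)."""
    norm = normalize_name(name)
    alpha, beta = norm.split("-", 1)
    return classify_pairing(alpha, beta, rules)


# ---------------------------------------------------------------------------
# pseudo-sequence distance


def pseudo_distance(pseudo_a: str, pseudo_b: str) -> float:
    """Normalized BLOSUM50 pseudo-sequence distance,
    d = 1 - s(A,B)/sqrt(s(A,A) s(B,B)) with s the summed position-wise score."""
    if len(pseudo_a) != len(pseudo_b):
        raise ValueError("pseudo-sequences must have equal length")
    ia, ib = seq_to_indices(pseudo_a), seq_to_indices(pseudo_b)
    sab = float(BLOSUM50[ia, ib].sum())
    saa = float(BLOSUM50[ia, ia].sum())
    sbb = float(BLOSUM50[ib, ib].sum())
    return 1.0 - sab / np.sqrt(saa * sbb)


def pseudo_distance_matrix(pseudos: dict[str, str]) -> pd.DataFrame:
    names = list(pseudos)
    mat = np.zeros((len(names), len(names)))
    for i, j in combinations(range(len(names)), 2):
        d = pseudo_distance(pseudos[names[i]], pseudos[names[j]])
        mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=names, columns=names)


# ---------------------------------------------------------------------------
# prevalent molecules from allele frequencies


def weighted_frequency(
    population_rows,
    cap: int = POPULATION_CAP,
    min_size: int = POPULATION_MIN_SIZE,
) -> float | None:
    """Worldwide allele frequency as a population-size-weighted average.

    Populations smaller than ``min_size`` are dropped; sizes are capped at
    ``cap`` so very large studies do not dominate.  None for empty input.
    """
    rows = [(f, n) for f, n in population_rows if n >= min_size]
    if not rows:
        return None
    w = np.array([min(n, cap) for _, n in rows], dtype=np.float64)
    f = np.array([f for f, _ in rows], dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("negative allele frequency")
    return float(np.sum(f * w) / np.sum(w))


def aggregate_frequencies(df: pd.DataFrame, **kwargs) -> dict[str, float]:
    """Collapse an ``allele,frequency,sample_size`` table to worldwide
    frequencies per allele; pre-aggregated tables (no sample_size) pass
    through."""
    if "sample_size" not in df:
        return dict(zip(df["allele"].map(normalize_name), df["frequency"].astype(float)))
    out = {}
    for allele, grp in df.groupby("allele"):
        wf = weighted_frequency(zip(grp["frequency"].astype(float), grp["sample_size"].astype(int)), **kwargs)
        if wf is not None:
            out[normalize_name(allele)] = wf
    return out


def enumerate_prevalent(
    dqa_freqs: dict[str, float],
    dqb_freqs: dict[str, float],
    rules: PairingRuleTable | None = None,
    threshold: float = PREVALENCE_THRESHOLD,
    combiner: str = "product",
) -> pd.DataFrame:
    """All rule-allowed high-resolution DQ pairs whose combined worldwide
    frequency strictly exceeds ``threshold``, sorted by frequency (descending).

    The combined frequency is the product of the chain frequencies by default
    (haplotype-independence assumption); ``combiner="min"`` uses the rarer
    chain instead.
    """
    rules = rules or PairingRuleTable()
    combine = {"product": lambda a, b: a * b, "min": min}[combiner]
    rows = []
    for a, fa in dqa_freqs.items():
        if fa < 0:
            raise ValueError(f"negative frequency for {a}")
        for b, fb in dqb_freqs.items():
            if fb < 0:
                raise ValueError(f"negative frequency for {b}")
            if (_group(a, "DQA1"), _group(b, "DQB1")) not in rules:
                continue
            combined = combine(fa, fb)
            if combined > threshold:
                rows.append(
                    {
                        "molecule": f"{normalize_name(a)}-{normalize_name(b)}",
                        "alpha": normalize_name(a),
                        "beta": normalize_name(b),
                        "frequency": combined,
                    }
                )
    df = pd.DataFrame(rows, columns=["molecule", "alpha", "beta", "frequency"])
    return df.sort_values("frequency", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# coverage


def coverage(
    annotations: pd.DataFrame,
    min_fraction: float = COVERAGE_MIN_FRACTION,
    min_total: int = COVERAGE_MIN_TOTAL,
) -> pd.DataFrame:
    """Accumulated per-molecule peptide counts over cell lines, with the
    low-count noise gate: a molecule's count in a cell line only enters its sum
    when it makes up at least ``min_fraction`` of that line's (non-trash) DQ
    peptides.  A molecule is covered when its accumulated count reaches
    ``min_total``."""
    df = annotations[~annotations["is_trash"]]
    if "target" in df:
        df = df[df["target"] == 1]
    totals: dict[str, int] = {}
    for sid, grp in df.groupby("sample_id"):
        line_total = len(grp)
        if line_total == 0:
            continue
        for mol, sub in grp.groupby("molecule"):
            if len(sub) / line_total >= min_fraction:
                totals[mol] = totals.get(mol, 0) + len(sub)
    rows = [
        {"molecule": m, "count": c, "covered": c >= min_total} for m, c in sorted(totals.items())
    ]
    return pd.DataFrame(rows, columns=["molecule", "count", "covered"])


def extended_coverage(
    coverage_report: pd.DataFrame,
    pseudos: dict[str, str],
    cutoff: float = EXTENDED_COVERAGE_CUTOFF,
) -> pd.DataFrame:
    """Extend coverage to molecules within pseudo-distance ``cutoff`` of a
    covered molecule.  ``pseudos`` lists every molecule of interest (covered
    molecules must be included); covered implies extended-covered."""
    covered = set(coverage_report.loc[coverage_report["covered"], "molecule"])
    counts = dict(zip(coverage_report["molecule"], coverage_report["count"]))
    rows = []
    for name, pseudo in pseudos.items():
        norm = normalize_name(name)
        if norm in covered:
            dist = 0.0
        else:
            dists = [pseudo_distance(pseudo, pseudos[c]) for c in covered if c in pseudos]
            dist = min(dists) if dists else np.inf
        rows.append(
            {
                "molecule": norm,
                "count": counts.get(norm, 0),
                "covered": norm in covered,
                "distance_to_covered": dist,
                "extended_covered": norm in covered or dist <= cutoff,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cis/trans contribution analysis


def contribution_analysis(
    annotations: pd.DataFrame,
    samples: dict,
    sa_molecules,
    rules: PairingRuleTable | None = None,
    min_dq: int = 100,
    heterozygous_only: bool = True,
) -> pd.DataFrame:
    """Mean per-dataset fraction of DQ annotations per molecule, by category.

    Only datasets with at least ``min_dq`` non-trash DQ-annotated peptides
    qualify.  For each qualifying dataset the fraction of its DQ annotations
    assigned to each expressed DQ molecule is computed; a molecule's
    contribution is the mean fraction over the qualifying datasets expressing
    it.  Categories: ``trans_only``, and cis split into ``cis_SA`` (molecule in
    the single-allelic training data) and ``cis_MA``.
    """
    rules = rules or PairingRuleTable()
    sa_molecules = {normalize_name(m) for m in sa_molecules}
    df = annotations[~annotations["is_trash"]]
    if "target" in df:
        df = df[df["target"] == 1]
    fractions: dict[str, list[float]] = {}
    for sid, grp in df.groupby("sample_id"):
        sample = samples[sid]
        dq_mols = [m for m in sample.molecules if "-" in normalize_name(m) and "DQ" in m]
        if heterozygous_only and len(dq_mols) < 2:
            continue
        dq_ann = grp[grp["molecule"].isin(dq_mols)]
        if len(dq_ann) < min_dq:
            continue
        for mol in dq_mols:
            frac = float((dq_ann["molecule"] == mol).mean())
            fractions.setdefault(normalize_name(mol), []).append(frac)
    rows = []
    for mol, fr in sorted(fractions.items()):
        cls = classify_molecule(mol, rules)
        category = cls if cls == "trans_only" else ("cis_SA" if mol in sa_molecules else "cis_MA")
        rows.append(
            {
                "molecule": mol,
                "category": category,
                "mean_fraction": float(np.mean(fr)),
                "n_datasets": len(fr),
            }
        )
    return pd.DataFrame(rows, columns=["molecule", "category", "mean_fraction", "n_datasets"])


def category_means(contrib: pd.DataFrame) -> dict[str, float]:
    """Summaries per category, with ``cis_all`` pooling both cis classes."""
    out = {}
    for cat in ("cis_SA", "cis_MA", "trans_only"):
        sub = contrib[contrib["category"] == cat]
        out[cat] = float(sub["mean_fraction"].mean()) if len(sub) else float("nan")
    cis = contrib[contrib["category"] != "trans_only"]
    out["cis_all"] = float(cis["mean_fraction"].mean()) if len(cis) else float("nan")
    return out


def select_representatives(
    pseudos: dict[str, str],
    covered=(),
    preferred=(),
    frequencies: dict[str, float] | None = None,
) -> dict[str, str]:
    """Reduce a molecule list to unique pseudo-sequences, one representative
    name per sequence.

    Priority within a duplicate group: a molecule covered by the training
    data, then a preferred (e.g. newly characterized) molecule, then the
    highest global frequency, then the lexicographically smallest name.
    Returns ``{representative name: pseudo-sequence}`` preserving priority.
    """
    covered = {normalize_name(m) for m in covered}
    preferred = {normalize_name(m) for m in preferred}
    frequencies = {normalize_name(k): v for k, v in (frequencies or {}).items()}
    groups: dict[str, list[str]] = {}
    for name, pseudo in pseudos.items():
        groups.setdefault(pseudo, []).append(normalize_name(name))

    def rank(name: str):
        return (
            0 if name in covered else 1,
            0 if name in preferred else 1,
            -frequencies.get(name, 0.0),
            name,
        )

    return {min(names, key=rank): pseudo for pseudo, names in groups.items()}


# ---------------------------------------------------------------------------
# specificity similarity and trees


def specificity_distance(
    ensemble,
    molecules,
    proteome: dict[str, str],
    n: int = 10000,
    lengths: tuple[int, int] = (13, 17),
    seed: int = 0,
) -> pd.DataFrame:
    """Functional distance between molecules: 1 - Pearson correlation of their
    prediction scores over one shared set of random natural peptides.

    A molecule with constant scores has undefined correlation; its off-diagonal
    distances are set to 1.  The matrix is symmetric with a zero diagonal.
    """
    molecules = [normalize_name(m) for m in molecules]
    rng = np.random.default_rng(seed)
    peptides = sample_natural_peptides(proteome, n, lengths, rng)
    scores = ensemble.score_matrix(peptides, molecules)
    sd = scores.std(axis=0)
    k = len(molecules)
    dist = np.ones((k, k))
    ok = sd > 0
    if ok.any():
        corr = np.corrcoef(scores[:, ok].T)
        dist[np.ix_(ok, ok)] = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return pd.DataFrame(dist, index=molecules, columns=molecules)


def build_tree(distance: pd.DataFrame) -> str:
    """Neighbor-joining specificity tree as a Newick string.

    Negative NJ branch lengths are clamped to 0.  With fewer than 3 leaves a
    degenerate Newick without internal structure is returned.
    """
    names = [str(c) for c in distance.columns]
    mat = np.asarray(distance, dtype=np.float64)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-9):
        raise ValueError("distance matrix must be square and symmetric")
    if len(names) == 1:
        return f"{names[0]};"
    if len(names) == 2:
        d = mat[0, 1] / 2.0
        return f"({names[0]}:{d:.6g},{names[1]}:{d:.6g});"
    from skbio import DistanceMatrix
    from skbio.tree import nj

    tree = nj(DistanceMatrix(mat, names))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()


def motif_logo_data(
    ensemble,
    molecule: str,
    proteome: dict[str, str],
    n: int = 10000,
    lengths: tuple[int, int] = (13, 17),
    top_frac: float = 0.01,
    seed: int = 0,
) -> Pssm:
    """Predicted binding-motif PSSM: score ``n`` random natural peptides, keep
    the top ``top_frac`` by score and build a PSSM from their predicted cores."""
    rng = np.random.default_rng(seed)
    peptides = sample_natural_peptides(proteome, n, lengths, rng)
    scores, offsets = ensemble.score_matrix(peptides, [molecule], return_offsets=True)
    k = max(1, int(round(n * top_frac)))
    top = np.argsort(-scores[:, 0], kind="stable")[:k]
    cores = [peptides[i][offsets[i, 0] : offsets[i, 0] + 9] for i in top]
    return build_pssm(cores)
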