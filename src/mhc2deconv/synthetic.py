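"""Fully synthetic immunopeptidome studies with known ground truth.

The generator emulates the structure of a class II MS-immunopeptidomics study:
a panel of DQ molecules with planted 9-mer binding motifs, single-allelic (SA)
and heterozygous multi-allelic (MA) cell-line samples whose positive peptides
embed motif-sampled cores in random flanks, a contaminant ("trash") fraction
drawn from pure background, random-natural negative enrichment, binding
affinity data, and — central to the cis/trans question — MA allele lists that
include the recombinant trans-only alpha/beta pairings, which generate zero
peptides.  Every draw is reproducible from the study seed.

Pseudo-sequences for cis molecules are derived deterministically from their
planted motifs (similar motifs get similar pseudo-sequences, so that
pseudo-distance analytics behave meaningfully); a trans molecule's
pseudo-sequence recombines the alpha 15-mer of one haplotype with the beta
19-mer of the other, exactly as a trans heterodimer recombines chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blosum import AMINO_ACIDS
from .datasets import Sample, enrich_negatives
from .hla import PseudoSequenceTable, normalize_name, split_pseudo

DEFAULT_ANCHORS = (1, 4, 6, 9)
DEFAULT_LENGTH_PROBS = {
    12: 0.05, 13: 0.09, 14: 0.21, 15: 0.19, 16: 0.13,
    17: 0.10, 18: 0.08, 19: 0.06, 20: 0.05, 21: 0.04,
}


@dataclass
class PlantedMotif:
    """A 9-position residue-probability matrix with concentrated anchor columns."""

    name: str
    matrix: np.ndarray  # (9, 20), rows sum to 1
    anchors: tuple[int, ...] = DEFAULT_ANCHORS
    strength: float = 10.0

    def column_entropy(self) -> np.ndarray:
        m = self.matrix
        return -np.sum(np.where(m > 0, m * np.log2(m), 0.0), axis=1)


def simulate_motif(
    seed,
    anchors: tuple[int, ...] = DEFAULT_ANCHORS,
    strength: float = 10.0,
    name: str = "",
) -> PlantedMotif:
    """Draw a planted motif; anchor columns (1-based positions) are Dirichlet
    with concentration 1/strength (point masses as strength -> inf), non-anchor
    columns near-uniform."""
    if not set(anchors) <= set(range(1, 10)):
        raise ValueError("anchor positions must lie in 1..9")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mat = np.empty((9, 20))
    for p in range(9):
        alpha = 1.0 / strength if (p + 1) in anchors else 5.0
        mat[p] = rng.dirichlet(np.full(20, alpha))
    return PlantedMotif(name=name, matrix=mat, anchors=tuple(anchors), strength=strength)


def motif_pseudo(motif: PlantedMotif) -> str:
    """Derive a deterministic 34-mer pseudo-sequence from a motif: position j
    carries the rank-(j // 9) residue of motif column j % 9, so Hamming-similar
    motifs map to Hamming-similar pseudo-sequences."""
    out = []
    for j in range(34):
        col = motif.matrix[j % 9]
        rank = j // 9
        out.append(AMINO_ACIDS[int(np.argsort(-col, kind="stable")[rank])])
    return "".join(out)


def trans_pseudo(pseudo_a: str, pseudo_b: str) -> str:
    """Pseudo-sequence of the trans pairing: alpha part of A + beta part of B."""
    return split_pseudo(pseudo_a)[0] + split_pseudo(pseudo_b)[1]


def trans_name(mol_a: str, mol_b: str) -> str:
    """Name of the alphaA/betaB recombinant of two combined molecule names."""
    alpha = normalize_name(mol_a).split("-")[0]
    beta = normalize_name(mol_b).split("-")[1]
    return f"{alpha}-{beta}"


@dataclass(frozen=True)
class MaSampleSpec:
    """A heterozygous sample: two cis haplotype molecules generate peptides;
    the two recombinant trans pairings are expressed in the allele list only."""

    sample_id: str
    haplotypes: tuple[str, str]
    weights: tuple[float, float] = (0.55, 0.45)
    n_pos: int = 700


@dataclass
class StudyConfig:
    """Study conditions of the default synthetic benchmark.

    Six cis molecules with single-allelic samples of 2000 positives each and
    three heterozygous MA samples mixing pairs of them, chosen so that all
    recombinant alpha/beta pairings in the MA allele lists are trans-only;
    peptide lengths 12-21 with the mode at 14-15, a 5% background-contaminant
    fraction and 5x-modal negative enrichment.  Restriction of all cis
    molecules to SA-anchored ones mirrors the real training corpus, where every
    deconvoluted cis specificity is ultimately anchored by single-allelic data.
    """

    sa_molecules: tuple[str, ...] = (
        "DQA10101-DQB10501",
        "DQA10102-DQB10602",
        "DQA10303-DQB10301",
        "DQA10501-DQB10201",
        "DQA10401-DQB10402",
        "DQA10201-DQB10202",
    )
    ma_only_molecules: tuple[str, ...] = ()
    sa_n_pos: int = 2000
    ma_samples: tuple[MaSampleSpec, ...] = (
        MaSampleSpec("MA1", ("DQA10101-DQB10501", "DQA10303-DQB10301"), (0.55, 0.45), 700),
        MaSampleSpec("MA2", ("DQA10102-DQB10602", "DQA10501-DQB10201"), (0.55, 0.45), 700),
        MaSampleSpec("MA3", ("DQA10201-DQB10202", "DQA10101-DQB10501"), (0.55, 0.45), 700),
    )
    length_probs: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_LENGTH_PROBS))
    trash_frac: float = 0.05
    negative_multiplier: int = 5
    n_ba_per_molecule: int = 250
    ba_lengths: tuple[int, int] = (13, 17)
    anchors: tuple[int, ...] = DEFAULT_ANCHORS
    motif_strength: float = 10.0
    max_motif_correlation: float = 0.3
    n_proteins: int = 50
    protein_length: int = 2000
    seed: int = 0

    def __post_init__(self):
        total = sum(self.length_probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"length probabilities sum to {total}, not 1")
        for spec in self.ma_samples:
            if not np.isclose(sum(spec.weights), 1.0):
                raise ValueError(f"{spec.sample_id}: mixture weights must sum to 1")
            for m in spec.haplotypes:
                if m not in self.sa_molecules and m not in self.ma_only_molecules:
                    raise ValueError(f"{spec.sample_id}: unknown molecule {m}")

    @property
    def generating_molecules(self) -> tuple[str, ...]:
        return self.sa_molecules + self.ma_only_molecules


@dataclass
class StudyBundle:
    """Everything a study produces: data frames in the pipeline's input
    formats plus the hidden ground truth."""

    el: pd.DataFrame  # peptide, target, sample_id
    ba: pd.DataFrame  # peptide, target, molecule
    samples: dict[str, Sample]
    pseudo_table: PseudoSequenceTable
    proteome: dict[str, str]
    truth: pd.DataFrame  # sample_id, peptide, molecule ("trash" for contaminants)
    motifs: dict[str, PlantedMotif]
    sa_molecules: tuple[str, ...]
    trans_molecules: tuple[str, ...]
    config: StudyConfig

    def write(self, outdir) -> None:
        from pathlib import Path

        from .datasets import write_peptide_tsv, write_proteome, write_sample_map

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_peptide_tsv(self.el, out / "el.tsv")
        self.ba.to_csv(out / "ba.tsv", sep="\t", header=False, index=False)
        write_sample_map(self.samples, out / "samples.tsv")
        self.pseudo_table.write(out / "pseudosequences.dat")
        write_proteome(self.proteome, out / "proteome.fasta")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def _sample_peptide(motif: np.ndarray, length: int, rng: np.random.Generator) -> str:
    """Embed a motif-sampled 9-mer core in uniform-background flanks at a
    uniform offset."""
    offset = int(rng.integers(0, length - 9 + 1))
    residues = rng.integers(0, 20, size=length)
    for p in range(9):
        residues[offset + p] = rng.choice(20, p=motif[p])
    return "".join(AMINO_ACIDS[i] for i in residues)


def _background_peptide(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def generate_motifs(config: StudyConfig) -> dict[str, PlantedMotif]:
    """Planted motifs for all generating molecules, redrawn until every pair's
    flattened correlation is below the configured separation target."""
    rng = np.random.default_rng([config.seed, 1])
    motifs: dict[str, PlantedMotif] = {}
    for name in config.generating_molecules:
        for _ in range(200):
            cand = simulate_motif(rng, config.anchors, config.motif_strength, name=name)
            flat = cand.matrix.reshape(-1)
            if all(
                np.corrcoef(flat, m.matrix.reshape(-1))[0, 1] < config.max_motif_correlation
                for m in motifs.values()
            ):
                break
        else:
            raise RuntimeError(f"could not draw a sufficiently distinct motif for {name}")
        motifs[name] = cand
    return motifs


def generate_sample(
    sample_id: str,
    mixture: list[tuple[str, PlantedMotif, float]],
    n_pos: int,
    length_probs: dict[int, float],
    trash_frac: float,
    proteome: dict[str, str],
    rng: np.random.Generator,
    negative_multiplier: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One sample's EL records (positives + enriched negatives) and its truth.

    The trash count is deterministic: ``round(trash_frac * n_pos)`` background
    peptides; the remaining positives draw a generating molecule from the
    mixture weights.
    """
    if n_pos <= 0:
        raise ValueError("n_pos must be positive")
    weights = np.array([w for _, _, w in mixture], dtype=np.float64)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("mixture weights must sum to 1")
    lengths = np.array(sorted(length_probs), dtype=np.int64)
    lprobs = np.array([length_probs[L] for L in lengths])
    n_trash = int(round(trash_frac * n_pos))
    n_true = n_pos - n_trash
    peptides: list[str] = []
    origins: list[str] = []
    mol_draws = rng.choice(len(mixture), size=n_true, p=weights)
    len_draws = lengths[rng.choice(len(lengths), size=n_pos, p=lprobs)]
    for i in range(n_true):
        name, motif, _ = mixture[mol_draws[i]]
        peptides.append(_sample_peptide(motif.matrix, int(len_draws[i]), rng))
        origins.append(name)
    for i in range(n_true, n_pos):
        peptides.append(_background_peptide(int(len_draws[i]), rng))
        origins.append("trash")
    positives = pd.DataFrame({"peptide": peptides, "target": 1.0, "sample_id": sample_id})
    negatives = enrich_negatives(
        positives, proteome, multiplier=negative_multiplier, seed=rng
    )
    el = pd.concat([positives, negatives], ignore_index=True)
    truth = pd.DataFrame({"sample_id": sample_id, "peptide": peptides, "molecule": origins})
    return el, truth


def generate_ba(
    molecule: str,
    motif: PlantedMotif,
    n: int,
    lengths: tuple[int, int],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Binding-affinity records: half motif-embedding binders with high
    transformed affinity, half background with low."""
    rows = []
    for i in range(n):
        L = int(rng.integers(lengths[0], lengths[1] + 1))
        if i < n // 2:
            pep = _sample_peptide(motif.matrix, L, rng)
            target = float(rng.uniform(0.6, 0.95))
        else:
            pep = _background_peptide(L, rng)
            target = float(rng.uniform(0.0, 0.3))
        rows.append({"peptide": pep, "target": target, "molecule": molecule})
    return pd.DataFrame(rows)


def generate_study(config: StudyConfig | None = None) -> StudyBundle:
    """Generate the full study bundle; byte-identical for a fixed config."""
    config = config or StudyConfig()
    rng_prot = np.random.default_rng([config.seed, 0])
    proteome = {
        f"PROT{i:03d}": _random_protein(rng_prot, config.protein_length)
        for i in range(config.n_proteins)
    }
    motifs = generate_motifs(config)

    pseudos: dict[str, str] = {name: motif_pseudo(m) for name, m in motifs.items()}
    samples: dict[str, Sample] = {}
    el_frames: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []
    trans: list[str] = []

    for i, mol in enumerate(config.sa_molecules):
        sid = f"SA{i + 1}"
        rng = np.random.default_rng([config.seed, 2, i])
        el, truth = generate_sample(
            sid,
            [(mol, motifs[mol], 1.0)],
            config.sa_n_pos,
            config.length_probs,
            config.trash_frac,
            proteome,
            rng,
            config.negative_multiplier,
        )
        samples[sid] = Sample(sid, (mol,))
        el_frames.append(el)
        truth_frames.append(truth)

    for i, spec in enumerate(config.ma_samples):
        rng = np.random.default_rng([config.seed, 3, i])
        mol_a, mol_b = spec.haplotypes
        t_ab, t_ba = trans_name(mol_a, mol_b), trans_name(mol_b, mol_a)
        for t, pa, pb in ((t_ab, mol_a, mol_b), (t_ba, mol_b, mol_a)):
            if t not in pseudos:
                pseudos[t] = trans_pseudo(pseudos[pa], pseudos[pb])
                trans.append(t)
        mixture = [
            (mol_a, motifs[mol_a], spec.weights[0]),
            (mol_b, motifs[mol_b], spec.weights[1]),
        ]
        el, truth = generate_sample(
            spec.sample_id,
            mixture,
            spec.n_pos,
            config.length_probs,
            config.trash_frac,
            proteome,
            rng,
            config.negative_multiplier,
        )
        samples[spec.sample_id] = Sample(spec.sample_id, (mol_a, mol_b, t_ab, t_ba))
        el_frames.append(el)
        truth_frames.append(truth)

    ba_frames = []
    for i, mol in enumerate(config.sa_molecules):
        rng = np.random.default_rng([config.seed, 4, i])
        ba_frames.append(
            generate_ba(mol, motifs[mol], config.n_ba_per_molecule, config.ba_lengths, rng)
        )
    ba = (
        pd.concat(ba_frames, ignore_index=True)
        if ba_frames
        else pd.DataFrame(columns=["peptide", "target", "molecule"])
    )

    return StudyBundle(
        el=pd.concat(el_frames, ignore_index=True),
        ba=ba,
        samples=samples,
        pseudo_table=PseudoSequenceTable(pseudos),
        proteome=proteome,
        truth=pd.concat(truth_frames, ignore_index=True),
        motifs=motifs,
        sa_molecules=config.sa_molecules,
        trans_molecules=tuple(trans),
        config=config,
    )
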