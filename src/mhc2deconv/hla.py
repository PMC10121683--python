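"""MHC class II molecule representation and pseudo-sequence handling.

A class II molecule is an alpha/beta heterodimer summarized for pan-specific
prediction by a 34-residue *pseudo-sequence*: the polymorphic, groove-proximal
positions of the two chains concatenated into one string, of which the first 15
residues derive from the alpha chain and the remaining 19 from the beta chain.
Pseudo-sequences are inherited data (two-column text files in the NetMHCIIpan
dialect), not something this package derives from full chain alignments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .blosum import is_standard

PSEUDO_LENGTH = 34
ALPHA_PART = 15
BETA_PART = 19


class PseudoSequenceError(ValueError):
    """Malformed, conflicting or invalid pseudo-sequence input."""


def normalize_name(name: str) -> str:
    """Normalize a class II molecule name to the compact canonical form.

    Strips the ``HLA-`` prefix, asterisks and colons: ``HLA-DQA1*01:01-DQB1*05:01``
    becomes ``DQA10101-DQB10501``.  DR names given in star/colon style are mapped
    to the underscore convention (``DRB1*01:01`` -> ``DRB1_0101``).  Idempotent.
    """
    s = name.strip()
    if s.upper().startswith("HLA-"):
        s = s[4:]
    s = s.replace("*", "").replace(":", "")
    m = re.fullmatch(r"(DRB\d)_?(\d+)", s)
    if m:
        s = f"{m.group(1)}_{m.group(2)}"
    return s


def locus_of(name: str) -> str:
    """Locus of a normalized molecule name: one of ``DR``, ``DQ``, ``DP``, ``other``."""
    s = normalize_name(name)
    if s.startswith("DRB") or s.startswith("DRA"):
        return "DR"
    if s.startswith("DQA") or s.startswith("DQB"):
        return "DQ"
    if s.startswith("DPA") or s.startswith("DPB"):
        return "DP"
    return "other"


@dataclass(frozen=True)
class Molecule:
    """A class II molecule with its pseudo-sequence.

    ``alpha_allele``/``beta_allele`` are compact allele names (e.g. ``DQA10101``);
    for monomorphic-alpha loci (DR) ``alpha_allele`` is empty.
    """

    name: str
    pseudo: str
    locus: str = field(default="")
    alpha_allele: str = field(default="")
    beta_allele: str = field(default="")

    def __post_init__(self):
        if len(self.pseudo) != PSEUDO_LENGTH:
            raise PseudoSequenceError(
                f"{self.name}: pseudo-sequence length {len(self.pseudo)} != {PSEUDO_LENGTH}"
            )
        if not is_standard(self.pseudo):
            raise PseudoSequenceError(f"{self.name}: pseudo-sequence contains non-standard letters")
        norm = normalize_name(self.name)
        object.__setattr__(self, "name", norm)
        if not self.locus:
            object.__setattr__(self, "locus", locus_of(norm))
        if not self.beta_allele:
            alpha, beta = _split_name(norm, self.locus)
            object.__setattr__(self, "alpha_allele", alpha)
            object.__setattr__(self, "beta_allele", beta)
        if self.locus in ("DQ", "DP") and not (self.alpha_allele and self.beta_allele):
            raise PseudoSequenceError(f"{self.name}: {self.locus} molecules need both chain alleles")


def _split_name(norm: str, locus: str) -> tuple[str, str]:
    if "-" in norm:
        alpha, beta = norm.split("-", 1)
        return alpha, beta
    if locus == "DR":
        return "", norm
    return "", norm


def split_pseudo(molecule: Molecule | str) -> tuple[str, str]:
    """Split a 34-mer pseudo-sequence into its (15-mer alpha, 19-mer beta) parts."""
    pseudo = molecule.pseudo if isinstance(molecule, Molecule) else molecule
    if len(pseudo) != PSEUDO_LENGTH:
        raise PseudoSequenceError(f"pseudo-sequence length {len(pseudo)} != {PSEUDO_LENGTH}")
    return pseudo[:ALPHA_PART], pseudo[ALPHA_PART:]


class PseudoSequenceTable:
    """Mapping of normalized molecule names to validated 34-mer pseudo-sequences."""

    def __init__(self, entries: dict[str, str] | None = None):
        self.entries: dict[str, str] = {}
        if entries:
            for name, pseudo in entries.items():
                self.add(name, pseudo)

    def add(self, name: str, pseudo: str) -> None:
        norm = normalize_name(name)
        if len(pseudo) != PSEUDO_LENGTH:
            raise PseudoSequenceError(
                f"{name}: pseudo-sequence length {len(pseudo)} != {PSEUDO_LENGTH}"
            )
        if not is_standard(pseudo):
            raise PseudoSequenceError(f"{name}: pseudo-sequence contains non-standard letters")
        old = self.entries.get(norm)
        if old is not None and old != pseudo:
            raise PseudoSequenceError(f"{name}: conflicting pseudo-sequences for duplicate name")
        self.entries[norm] = pseudo

    def __getitem__(self, name: str) -> str:
        return self.entries[normalize_name(name)]

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def molecule(self, name: str) -> Molecule:
        norm = normalize_name(name)
        return Molecule(name=norm, pseudo=self.entries[norm])

    def names(self) -> list[str]:
        return list(self.entries)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for name, pseudo in self.entries.items():
                fh.write(f"{name} {pseudo}\n")


def load_pseudosequences(path) -> PseudoSequenceTable:
    """Read a two-column whitespace-delimited ``<molecule> <34-mer>`` file.

    Duplicate names with identical sequences collapse to one entry; conflicting
    duplicates, wrong-length sequences and malformed lines raise
    :class:`PseudoSequenceError` naming the offending line or molecule.
    """
    table = PseudoSequenceTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2:
                raise PseudoSequenceError(
                    f"{path}:{lineno}: expected 2 whitespace-delimited fields, got {len(fields)}"
                )
            table.add(fields[0], fields[1])
    return table
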