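"""Input encoding for the core-scanning networks.

Each peptide is evaluated at every 9-mer core register (offsets 0..L-9).  The
input presented to a network for one (peptide, offset, molecule) combination is
the concatenation of

* the 9 core residues, BLOSUM50-encoded (scores / 5), 180 values;
* peptide-flanking-region (PFR) composition: the mean BLOSUM encoding of up to
  3 residues on each side of the core inside the peptide (zeros when the core
  touches the peptide terminus), 40 values;
* a one-hot encoding of the peptide length over the ligand window 12-21;
* optionally the 12-mer source-protein context, BLOSUM-encoded, 240 values;
* the molecule's 34-mer pseudo-sequence, BLOSUM-encoded, 680 values.

The pseudo-sequence block enters the first layer linearly, so its contribution
to the hidden pre-activation can be cached per molecule; encodings are therefore
split into a "non-pseudo" part (stored per peptide and offset) and a pseudo part
(stored per molecule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blosum import BLOSUM50_SCALED, seq_to_indices

CORE_LENGTH = 9


@dataclass(frozen=True)
class EncodingConfig:
    core_length: int = CORE_LENGTH
    pfr_length: int = 3
    lengths: tuple[int, int] = (12, 21)
    use_context: bool = False
    context_length: int = 12

    @property
    def n_length_bins(self) -> int:
        return self.lengths[1] - self.lengths[0] + 1

    @property
    def np_dim(self) -> int:
        """Dimension of the non-pseudo-sequence input block."""
        d = 20 * self.core_length + 2 * 20 + self.n_length_bins
        if self.use_context:
            d += 20 * self.context_length
        return d

    @property
    def pseudo_dim(self) -> int:
        return 20 * 34

    def length_onehot(self, length: int) -> np.ndarray:
        lo, hi = self.lengths
        v = np.zeros(self.n_length_bins, dtype=np.float32)
        v[min(max(length, lo), hi) - lo] = 1.0
        return v


def encode_pseudo(pseudo: str) -> np.ndarray:
    """BLOSUM-encode a 34-mer pseudo-sequence to a 680-vector (float32)."""
    idx = seq_to_indices(pseudo)
    if idx.size != 34:
        raise ValueError(f"pseudo-sequence must be 34 residues, got {idx.size}")
    return BLOSUM50_SCALED[idx].reshape(-1).astype(np.float32)


@dataclass
class LengthGroup:
    """All peptides of one length, encoded for every core offset.

    ``X`` has shape ``(n_peptides, n_offsets, np_dim)`` so a record's rows are
    contiguous; ``rec_idx`` maps group-local rows back to the caller's record
    indices.
    """

    length: int
    rec_idx: np.ndarray  # (n,)
    X: np.ndarray  # (n, n_off, np_dim) float32

    @property
    def n_offsets(self) -> int:
        return self.X.shape[1]


def encode_groups(
    peptides,
    config: EncodingConfig,
    contexts=None,
) -> list[LengthGroup]:
    """Encode peptides into per-length groups; raises for peptides shorter than
    the core length."""
    peptides = list(peptides)
    if contexts is not None:
        contexts = list(contexts)
    by_len: dict[int, list[int]] = {}
    for i, p in enumerate(peptides):
        if len(p) < config.core_length:
            raise ValueError(f"peptide {p!r} shorter than the {config.core_length}-mer core")
        by_len.setdefault(len(p), []).append(i)

    B = BLOSUM50_SCALED.astype(np.float32)
    groups: list[LengthGroup] = []
    for L in sorted(by_len):
        recs = np.array(by_len[L], dtype=np.int64)
        n = recs.size
        idx = np.empty((n, L), dtype=np.int64)
        for r, i in enumerate(recs):
            idx[r] = seq_to_indices(peptides[i])
        n_off = L - config.core_length + 1
        X = np.zeros((n, n_off, config.np_dim), dtype=np.float32)
        core_dim = 20 * config.core_length
        len_vec = EncodingConfig.length_onehot(config, L)
        ctx_block = None
        if config.use_context:
            ctx_block = np.empty((n, 20 * config.context_length), dtype=np.float32)
            for r, i in enumerate(recs):
                ctx = contexts[i] if contexts is not None else None
                if ctx is None or len(ctx) != config.context_length:
                    raise ValueError(f"missing or malformed context for peptide {peptides[i]!r}")
                ctx_block[r] = B[seq_to_indices(ctx)].reshape(-1)
        for o in range(n_off):
            core = B[idx[:, o : o + config.core_length]].reshape(n, core_dim)
            X[:, o, :core_dim] = core
            # PFR composition, N- then C-terminal
            w = min(config.pfr_length, o)
            if w > 0:
                X[:, o, core_dim : core_dim + 20] = B[idx[:, o - w : o]].mean(axis=1)
            w = min(config.pfr_length, L - config.core_length - o)
            if w > 0:
                X[:, o, core_dim + 20 : core_dim + 40] = B[
                    idx[:, o + config.core_length : o + config.core_length + w]
                ].mean(axis=1)
            X[:, o, core_dim + 40 : core_dim + 40 + config.n_length_bins] = len_vec
            if ctx_block is not None:
                X[:, o, core_dim + 40 + config.n_length_bins :] = ctx_block
        groups.append(LengthGroup(length=L, rec_idx=recs, X=X))
    return groups
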