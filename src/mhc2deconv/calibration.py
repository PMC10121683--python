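"""Percentile-rank calibration of prediction scores.

Raw network scores are not comparable between molecules, so each molecule's
score distribution is anchored to a sample of random natural peptides: a
percentile rank of 1 means 1% of the random peptides scored higher for that
molecule.  Ranks use strictly-greater counting, so ties rank favourably.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import sample_natural_peptides


@dataclass
class RankCalibration:
    """Sorted (descending) score sample of random natural peptides for one molecule."""

    scores: np.ndarray
    lengths: tuple[int, int] = (12, 21)
    _ascending: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.scores = np.sort(np.asarray(self.scores, dtype=np.float64))[::-1]
        self._ascending = self.scores[::-1].copy()

    @property
    def n(self) -> int:
        return self.scores.size


def build_calibrations(
    ensemble,
    molecules,
    proteome: dict[str, str],
    n: int = 10000,
    lengths: tuple[int, int] = (12, 21),
    seed: int = 0,
) -> dict[str, RankCalibration]:
    """Calibrations for several molecules from one shared random-peptide draw.

    Sharing the draw (deterministic in ``seed``) guarantees that molecules with
    identical pseudo-sequences receive identical calibrations.
    """
    if not getattr(ensemble, "members", None):
        raise ValueError("cannot calibrate an empty ensemble")
    rng = np.random.default_rng(seed)
    peptides = sample_natural_peptides(proteome, n, lengths, rng)
    scores = ensemble.score_matrix(peptides, list(molecules))
    return {
        mol: RankCalibration(scores=scores[:, j], lengths=lengths)
        for j, mol in enumerate(molecules)
    }


def build_calibration(
    ensemble,
    molecule: str,
    proteome: dict[str, str],
    n: int = 10000,
    lengths: tuple[int, int] = (12, 21),
    seed: int = 0,
) -> RankCalibration:
    return build_calibrations(ensemble, [molecule], proteome, n=n, lengths=lengths, seed=seed)[
        molecule
    ]


def percentile_rank(score, cal: RankCalibration):
    """Percentile rank(s) in [0, 100]: 100 x (#calibration scores strictly
    greater than ``score``) / N.  Accepts a scalar or an array."""
    if cal.n == 0:
        raise ValueError("empty calibration")
    score = np.asarray(score, dtype=np.float64)
    greater = cal.n - np.searchsorted(cal._ascending, score, side="right")
    rank = 100.0 * greater / cal.n
    return float(rank) if rank.ndim == 0 else rank
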