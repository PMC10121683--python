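"""NNAlign_MA-style training of core-scanning networks on mixed EL/BA data.

The model is an ensemble of small feed-forward networks (one hidden layer of 40
or 60 sigmoid units, two sigmoid output units — one for eluted-ligand data, one
for binding affinity).  Every network scans all 9-mer core registers of a
peptide and is trained on the highest-scoring one.  Multi-allelic (MA) samples
are handled by pseudo-labelling: after a burn-in period in which only
single-allelic (SA) and affinity data contribute, each MA record is re-annotated
every epoch to the expressed molecule giving the highest current prediction and
trained against that molecule; MA negatives likewise count against the
highest-scoring molecule.  Members of the ensemble differ by hidden-layer size,
weight-initialization seed and cross-validation fold; the ensemble prediction
is the arithmetic mean of the member outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import Sample
from .encoding import EncodingConfig, LengthGroup, encode_groups, encode_pseudo
from .hla import PseudoSequenceTable, normalize_name


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class TrainingConfig:
    """Hyperparameters of the NNAlign_MA training scheme.

    Defaults are the published full-scale settings: 300 epochs of constant-rate
    (0.05) stochastic gradient descent without early stopping, a 20-epoch SA
    burn-in, 10 weight initializations per architecture (40 and 60 hidden
    units) and 5 cross-validation folds — an ensemble of 100 networks.
    ``desk()`` returns the scaled-down preset used throughout the test suite.
    """

    epochs: int = 300
    burn_in_epochs: int = 20
    learning_rate: float = 0.05
    n_seeds: int = 10
    hidden_sizes: tuple[int, ...] = (40, 60)
    n_folds: int = 5
    batch_size: int = 32
    grad_aggregation: str = "sum"  # "sum" mimics online SGD; "mean" averages the batch
    ba_weight: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.burn_in_epochs > self.epochs and self.epochs > 0:
            raise ValueError("burn_in_epochs must not exceed epochs")

    @classmethod
    def desk(cls, **overrides) -> "TrainingConfig":
        """Desk-scale preset: 2 architectures x 2 seeds x 5 folds = 20 networks,
        20 epochs with a 3-epoch burn-in."""
        cfg = cls(epochs=20, burn_in_epochs=3, n_seeds=2)
        return replace(cfg, **overrides)


@dataclass
class NetworkWeights:
    """Weights of one member network; the first layer is split into the
    non-pseudo block and the pseudo-sequence block (see encoding module)."""

    W1np: np.ndarray  # (hidden, np_dim)
    W1p: np.ndarray  # (hidden, 680)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (2, hidden)  rows: EL unit, BA unit
    b2: np.ndarray  # (2,)

    @property
    def hidden_size(self) -> int:
        return self.W1np.shape[0]


def init_network(hidden: int, np_dim: int, rng: np.random.Generator) -> NetworkWeights:
    # float32 throughout: halves the SGD matmul cost, ample precision for SGD
    u = lambda *shape: rng.uniform(-0.05, 0.05, size=shape).astype(np.float32)
    return NetworkWeights(
        W1np=u(hidden, np_dim),
        W1p=u(hidden, 680),
        b1=u(hidden),
        W2=u(2, hidden),
        b2=u(2),
    )


@dataclass
class Member:
    hidden_size: int
    seed_index: int
    fold: int
    weights: NetworkWeights


# ---------------------------------------------------------------------------
# training data preparation


@dataclass
class _Stream:
    """Records sharing length group, candidate molecule set and output unit —
    the unit of vectorized batching."""

    group: int  # index into encoded groups
    local_idx: np.ndarray  # rows within the group
    cand: tuple[int, ...]  # candidate molecule indices
    unit: int  # 0 = EL, 1 = BA
    is_ma_el: bool
    targets: np.ndarray
    folds: np.ndarray


@dataclass
class TrainingData:
    groups: list[LengthGroup]
    streams: list[_Stream]
    molecules: list[str]
    P: np.ndarray  # (n_mol, 680) encoded pseudo-sequences
    config: EncodingConfig


def prepare_training_data(
    el: pd.DataFrame,
    ba: pd.DataFrame | None,
    samples: dict[str, Sample],
    partitioning,
    pseudo_table: PseudoSequenceTable,
    config: EncodingConfig | None = None,
) -> TrainingData:
    """Encode all records once and group them into vectorizable streams.

    ``el`` columns: peptide, target, sample_id (+context if the config uses it);
    ``ba`` columns: peptide, target, molecule.  Every sample molecule must
    resolve in the pseudo-sequence table (checked before any training starts).
    """
    config = config or EncodingConfig()
    mol_names: list[str] = []
    mol_index: dict[str, int] = {}

    def mol_id(name: str) -> int:
        norm = normalize_name(name)
        if norm not in mol_index:
            if norm not in pseudo_table:
                raise KeyError(f"molecule {name!r} has no pseudo-sequence")
            mol_index[norm] = len(mol_names)
            mol_names.append(norm)
        return mol_index[norm]

    for s in samples.values():
        for m in s.molecules:
            mol_id(m)

    peptides: list[str] = []
    contexts: list[str | None] = []
    meta: list[tuple[tuple[int, ...], int, bool, float, int]] = []  # cand, unit, ma, target, fold

    def fold_of(pep: str) -> int:
        try:
            return partitioning.assignment[pep]
        except KeyError:
            raise KeyError(f"peptide {pep!r} missing from the partitioning") from None

    for r in el.itertuples():
        sample = samples[str(r.sample_id)]
        cand = tuple(sorted(mol_id(m) for m in sample.molecules))
        peptides.append(r.peptide)
        contexts.append(getattr(r, "context", None))
        meta.append((cand, 0, sample.kind == "MA", float(r.target), fold_of(r.peptide)))
    if ba is not None:
        for r in ba.itertuples():
            peptides.append(r.peptide)
            contexts.append(None)
            meta.append(((mol_id(r.molecule),), 1, False, float(r.target), fold_of(r.peptide)))

    groups = encode_groups(peptides, config, contexts if config.use_context else None)
    streams: list[_Stream] = []
    for gi, g in enumerate(groups):
        keys: dict[tuple, list[int]] = {}
        for local, rec in enumerate(g.rec_idx):
            cand, unit, ma, _, _ = meta[rec]
            keys.setdefault((cand, unit, ma), []).append(local)
        for (cand, unit, ma), locals_ in sorted(keys.items()):
            locals_ = np.array(locals_, dtype=np.int64)
            recs = g.rec_idx[locals_]
            streams.append(
                _Stream(
                    group=gi,
                    local_idx=locals_,
                    cand=cand,
                    unit=unit,
                    is_ma_el=ma,
                    targets=np.array([meta[r][3] for r in recs], dtype=np.float32),
                    folds=np.array([meta[r][4] for r in recs], dtype=np.int64),
                )
            )
    P = np.stack([encode_pseudo(pseudo_table[m]) for m in mol_names])
    return TrainingData(groups=groups, streams=streams, molecules=mol_names, P=P, config=config)


# ---------------------------------------------------------------------------
# member training


def train_member(
    data: TrainingData,
    hidden: int,
    seed_index: int,
    fold: int,
    config: TrainingConfig,
    hook=None,
) -> NetworkWeights:
    """Train one network on all records outside ``fold``.

    ``hook(epoch, counts)`` is called after every epoch with the number of
    records that produced gradient updates, keyed by class
    (``SA_EL``/``MA_EL``/``BA``) — used to verify the burn-in contract.
    """
    rng = np.random.default_rng([config.seed, hidden, seed_index, fold])
    net = init_network(hidden, data.config.np_dim, rng)
    P = data.P  # float32
    lr = np.float32(config.learning_rate)

    stream_train_idx = [np.nonzero(s.folds != fold)[0] for s in data.streams]

    for epoch in range(1, config.epochs + 1):
        counts = {"SA_EL": 0, "MA_EL": 0, "BA": 0}
        chunks: list[tuple[int, np.ndarray]] = []
        for si, s in enumerate(data.streams):
            if s.is_ma_el and epoch <= config.burn_in_epochs:
                continue
            idx = stream_train_idx[si]
            if idx.size == 0:
                continue
            perm = idx[rng.permutation(idx.size)]
            for start in range(0, perm.size, config.batch_size):
                chunks.append((si, perm[start : start + config.batch_size]))
        order = rng.permutation(len(chunks))
        for ci in order:
            si, batch = chunks[ci]
            s = data.streams[si]
            _sgd_step(net, data, s, batch, P, lr, config)
            key = "BA" if s.unit == 1 else ("MA_EL" if s.is_ma_el else "SA_EL")
            counts[key] += batch.size
        if hook is not None:
            hook(epoch, counts)
    return net


def _sgd_step(net, data, s: _Stream, batch, P, lr, config) -> None:
    g = data.groups[s.group]
    b = batch.size
    n_off = g.n_offsets
    X = g.X[s.local_idx[batch]].reshape(b * n_off, -1)
    Z = X @ net.W1np.T + net.b1  # (R, h)
    cand = s.cand
    zp = P[list(cand)] @ net.W1p.T  # (c, h)
    w2, b2o = net.W2[s.unit], net.b2[s.unit]

    H = _sigmoid(Z[None, :, :] + zp[:, None, :])  # (c, R, h)
    out = _sigmoid(H @ w2 + b2o)  # (c, R)
    S = out.reshape(len(cand), b, n_off)
    best = np.argmax(S.transpose(1, 0, 2).reshape(b, -1), axis=1)
    sel_m, sel_o = np.divmod(best, n_off)

    rows = np.arange(b) * n_off + sel_o
    Hsel = H[sel_m, rows]  # (b, h)
    out_sel = out[sel_m, rows]
    t = s.targets[batch]
    weight = np.float32(config.ba_weight if s.unit == 1 else 1.0)
    delta2 = (out_sel - t) * out_sel * (np.float32(1.0) - out_sel) * weight  # (b,)
    dH = delta2[:, None] * w2[None, :]
    dZ = dH * Hsel * (np.float32(1.0) - Hsel)  # (b, h)
    Xsel = X[rows]

    scale = lr / np.float32(b) if config.grad_aggregation == "mean" else lr
    net.W2[s.unit] -= scale * (delta2 @ Hsel)
    net.b2[s.unit] -= scale * delta2.sum()
    net.W1np -= scale * (dZ.T @ Xsel)
    net.b1 -= scale * dZ.sum(axis=0)
    for ui, m in enumerate(cand):
        mask = sel_m == ui
        if mask.any():
            net.W1p -= scale * np.outer(dZ[mask].sum(axis=0), P[m])


# ---------------------------------------------------------------------------
# scoring


def _member_scores_groups(
    net: NetworkWeights,
    groups: list[LengthGroup],
    P: np.ndarray,
    n_records: int,
    unit: int = 0,
    collect_offset_sums: bool = False,
):
    """Per-record (max over core offsets) scores of one network for every
    molecule row in P.  Returns (scores (n_records, n_mol), per-offset score
    arrays for offset voting if requested)."""
    n_mol = P.shape[0]
    scores = np.zeros((n_records, n_mol), dtype=np.float64)
    offsets = []  # list of (group, per-offset array (n_mol, n, n_off)) if requested
    zp = P @ net.W1p.T  # (n_mol, h)
    for g in groups:
        n, n_off, _ = g.X.shape
        X = g.X.reshape(n * n_off, -1)
        Z = X @ net.W1np.T.astype(X.dtype) + net.b1
        per_off = np.empty((n_mol, n, n_off), dtype=np.float64)
        for m in range(n_mol):
            H = _sigmoid(Z + zp[m])
            out = _sigmoid(H @ net.W2[unit] + net.b2[unit])
            per_off[m] = out.reshape(n, n_off)
        scores[g.rec_idx] = per_off.max(axis=2).T
        if collect_offset_sums:
            offsets.append(per_off)
    return scores, offsets


@dataclass
class EnsembleModel:
    """A trained ensemble plus everything needed to score new peptides."""

    members: list[Member]
    encoding: EncodingConfig
    training: TrainingConfig
    pseudo_table: PseudoSequenceTable
    calibrations: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.members:
            raise ValueError("empty ensemble")

    # -- scoring ------------------------------------------------------------

    def score_matrix(
        self,
        peptides,
        molecules,
        contexts=None,
        peptide_folds=None,
        unit: int = 0,
        return_offsets: bool = False,
    ):
        """Ensemble scores for every (peptide, molecule) pair.

        Each member's score is the maximum over core offsets; the ensemble
        score is the mean over members.  When ``peptide_folds`` is given (array
        of cross-validation fold per peptide), a member trained with fold f
        held out contributes only to peptides of fold f, yielding honest
        concatenated cross-validation predictions.
        """
        peptides = list(peptides)
        mol_names = [normalize_name(m) for m in molecules]
        P = np.stack([encode_pseudo(self.pseudo_table[m]) for m in mol_names])
        groups = encode_groups(peptides, self.encoding, contexts)
        n = len(peptides)
        total = np.zeros((n, len(mol_names)), dtype=np.float64)
        counts = np.zeros(n, dtype=np.float64)
        off_sums = None
        if return_offsets:
            off_sums = [np.zeros((len(mol_names),) + g.X.shape[:2]) for g in groups]
        if peptide_folds is not None:
            peptide_folds = np.asarray(peptide_folds)
        for member in self.members:
            if peptide_folds is None:
                mask = np.ones(n, dtype=bool)
            else:
                mask = peptide_folds == member.fold
                if not mask.any():
                    continue
            scores, per_off = _member_scores_groups(
                member.weights, groups, P, n, unit=unit, collect_offset_sums=return_offsets
            )
            total[mask] += scores[mask]
            counts[mask] += 1.0
            if return_offsets:
                for gi, g in enumerate(groups):
                    gmask = mask[g.rec_idx]
                    off_sums[gi][:, gmask, :] += per_off[gi][:, gmask, :]
        if np.any(counts == 0):
            raise ValueError("some peptides have no contributing ensemble member")
        result = total / counts[:, None]
        if not return_offsets:
            return result
        core_offsets = np.zeros((n, len(mol_names)), dtype=np.int64)
        for gi, g in enumerate(groups):
            core_offsets[g.rec_idx] = off_sums[gi].argmax(axis=2).T
        return result, core_offsets

    def predict(self, peptide: str, molecule: str, context: str | None = None) -> float:
        """Ensemble EL score for a single peptide/molecule pair."""
        ctx = [context] if context is not None else None
        return float(self.score_matrix([peptide], [molecule], contexts=ctx)[0, 0])

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        import json

        payload = {
            "format": "mhc2deconv-ensemble-v1",
            "encoding": {
                "core_length": self.encoding.core_length,
                "pfr_length": self.encoding.pfr_length,
                "lengths": list(self.encoding.lengths),
                "use_context": self.encoding.use_context,
            },
            "training": {
                "epochs": self.training.epochs,
                "burn_in_epochs": self.training.burn_in_epochs,
                "learning_rate": self.training.learning_rate,
                "n_seeds": self.training.n_seeds,
                "hidden_sizes": list(self.training.hidden_sizes),
                "n_folds": self.training.n_folds,
                "batch_size": self.training.batch_size,
                "grad_aggregation": self.training.grad_aggregation,
                "ba_weight": self.training.ba_weight,
                "seed": self.training.seed,
            },
            "pseudo": dict(self.pseudo_table.entries),
            "members": [
                {
                    "hidden_size": m.hidden_size,
                    "seed_index": m.seed_index,
                    "fold": m.fold,
                    "weights": {
                        k: getattr(m.weights, k).tolist()
                        for k in ("W1np", "W1p", "b1", "W2", "b2")
                    },
                }
                for m in self.members
            ],
            "calibrations": {
                name: {"scores": cal.scores.tolist(), "lengths": list(cal.lengths)}
                for name, cal in self.calibrations.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        import json

        from .calibration import RankCalibration

        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "mhc2deconv-ensemble-v1":
            raise ValueError(f"{path}: not a recognised model container")
        enc = payload["encoding"]
        encoding = EncodingConfig(
            core_length=enc["core_length"],
            pfr_length=enc["pfr_length"],
            lengths=tuple(enc["lengths"]),
            use_context=enc["use_context"],
        )
        tr = payload["training"]
        training = TrainingConfig(
            epochs=tr["epochs"],
            burn_in_epochs=tr["burn_in_epochs"],
            learning_rate=tr["learning_rate"],
            n_seeds=tr["n_seeds"],
            hidden_sizes=tuple(tr["hidden_sizes"]),
            n_folds=tr["n_folds"],
            batch_size=tr["batch_size"],
            grad_aggregation=tr["grad_aggregation"],
            ba_weight=tr["ba_weight"],
            seed=tr["seed"],
        )
        members = [
            Member(
                hidden_size=m["hidden_size"],
                seed_index=m["seed_index"],
                fold=m["fold"],
                weights=NetworkWeights(
                    **{k: np.array(v, dtype=np.float32) for k, v in m["weights"].items()}
                ),
            )
            for m in payload["members"]
        ]
        model = cls(
            members=members,
            encoding=encoding,
            training=training,
            pseudo_table=PseudoSequenceTable(payload["pseudo"]),
        )
        for name, cal in payload.get("calibrations", {}).items():
            model.calibrations[name] = RankCalibration(
                scores=np.array(cal["scores"], dtype=np.float64),
                lengths=tuple(cal["lengths"]),
            )
        return model


def score_peptide(
    net: NetworkWeights,
    peptide: str,
    pseudo: str,
    config: EncodingConfig | None = None,
    context: str | None = None,
    unit: int = 0,
) -> tuple[float, int]:
    """Score one peptide with one network: max over all 9-mer core offsets.

    Returns ``(score, core_offset)``; ties go to the smallest offset (numpy
    argmax convention).  Raises for peptides shorter than the core.
    """
    config = config or EncodingConfig()
    groups = encode_groups([peptide], config, [context] if context is not None else None)
    g = groups[0]
    X = g.X.reshape(g.X.shape[1], -1).astype(np.float64)
    zp = encode_pseudo(pseudo).astype(np.float64) @ net.W1p.T
    H = _sigmoid(X @ net.W1np.T + net.b1 + zp)
    out = _sigmoid(H @ net.W2[unit] + net.b2[unit])
    off = int(np.argmax(out))
    return float(out[off]), off


def train(
    el: pd.DataFrame,
    ba: pd.DataFrame | None,
    samples: dict[str, Sample],
    partitioning,
    pseudo_table: PseudoSequenceTable,
    encoding: EncodingConfig | None = None,
    config: TrainingConfig | None = None,
    hook=None,
) -> EnsembleModel:
    """Train the full ensemble: every (architecture, seed, fold) combination.

    ``hook(member, epoch, counts)`` is forwarded to each member's training loop.
    """
    encoding = encoding or EncodingConfig()
    config = config or TrainingConfig()
    data = prepare_training_data(el, ba, samples, partitioning, pseudo_table, encoding)
    members: list[Member] = []
    for hidden in config.hidden_sizes:
        for seed_index in range(config.n_seeds):
            for fold in range(config.n_folds):
                member_hook = None
                if hook is not None:
                    member_hook = (
                        lambda epoch, counts, h=hidden, s=seed_index, f=fold: hook(
                            (h, s, f), epoch, counts
                        )
                    )
                net = train_member(data, hidden, seed_index, fold, config, hook=member_hook)
                members.append(Member(hidden, seed_index, fold, net))
    table = PseudoSequenceTable({m: pseudo_table[m] for m in data.molecules})
    return EnsembleModel(
        members=members, encoding=encoding, training=config, pseudo_table=table
    )
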