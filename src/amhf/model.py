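"""Fusion, training and the scikit-learn style classifier.

:class:`MultiFunctionPeptideClassifier` glues the three granularity
branches together: atomic (SMILES + transformer encoder), sequence
(embedding + MHSA + TextCNN over residues and Chou-Fasman structure) and
relational (k-mer hypergraph attention).  Branch features are concatenated
and passed through fully connected fusion layers with a per-class sigmoid;
labels are assigned by thresholding at 0.5 (ties count as positive).  Any
subset of branches can be enabled, matching the published ablations
(atomic / sequence / hypergraph alone or in combination).

Training minimizes class-weighted binary cross-entropy (weight
N / (M * count_c), countering class imbalance) with AdamW, linear warmup
and decoupled weight decay, end to end through all enabled branches.
The documented defaults keep the published settings (sequence length 50,
embedding 192, filters 2-5, k = 5, threshold 0.5, batch 128, learning
rate 5e-6, 30 epochs); :func:`tiny_classifier` provides a small
random-initialized configuration that trains in minutes on one CPU.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import _nn
from ._tensor import Tensor, concat, dropout
from .atomic import AtomicBranch, SmilesVocabulary, TinyTransformerEncoder, peptide_to_smiles, tokenize_smiles
from .hypergraph import Hypergraph, HyperGATBranch, build_hypergraph, inference_hypergraph, subgraph
from .io import LABEL_NAMES, PeptideRecord
from .metrics import MetricsReport, multilabel_metrics
from .sequence import SequenceBranch, encode_batch

__all__ = [
    "MultiFunctionPeptideClassifier",
    "FusionHead",
    "fuse_forward",
    "multilabel_loss",
    "train_model",
    "predict_records",
    "PredictionResult",
    "branch_combination",
    "tiny_classifier",
    "BRANCH_NAMES",
]

#: published ablation digits -> branch names (1 atomic, 2 sequence, 3 hypergraph)
BRANCH_NAMES = {"1": "atomic", "2": "sequence", "3": "hypergraph"}


def branch_combination(digits: str) -> tuple[str, ...]:
    """Map an ablation name like ``"23"`` to the branch tuple it enables."""
    if not digits or any(d not in BRANCH_NAMES for d in digits):
        raise ValueError(f"invalid branch combination {digits!r}")
    return tuple(BRANCH_NAMES[d] for d in digits)


class FusionHead(_nn.Module):
    """Concatenation -> FC stack (ReLU + dropout) -> sigmoid over classes."""

    def __init__(
        self,
        d_in: int,
        fc_layers: tuple[int, ...],
        n_classes: int,
        dropout_rate: float,
        rng: np.random.Generator,
    ):
        if d_in <= 0:
            raise ValueError("fusion head needs at least one enabled branch")
        widths = [d_in, *fc_layers]
        self.hidden = [_nn.Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]
        self.out = _nn.Linear(widths[-1], n_classes, rng)
        self.dropout_rate = dropout_rate

    def __call__(
        self,
        features: list[Tensor],
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        if not features:
            raise ValueError("fusion head received no branch features")
        h = concat(features, axis=-1) if len(features) > 1 else features[0]
        rng = rng if rng is not None else np.random.default_rng(0)
        for layer in self.hidden:
            h = dropout(layer(h).relu(), self.dropout_rate, rng, training)
        return self.out(h).sigmoid()


def fuse_forward(
    features: list[np.ndarray | Tensor | None],
    head: FusionHead,
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the fusion head to branch features (``None`` = branch disabled).

    Returns (probabilities, binary labels); a probability equal to the
    threshold counts as positive.
    """
    active = [f if isinstance(f, Tensor) else Tensor(f) for f in features if f is not None]
    if not active:
        raise ValueError("all branches disabled")
    probs = head(active, training=False).data
    return probs, (probs >= threshold).astype(np.int8)


def multilabel_loss(
    probabilities: Tensor | np.ndarray,
    true_labels: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> Tensor:
    """Mean class-weighted binary cross-entropy over samples and classes.

    Probabilities are clamped to [1e-7, 1 - 1e-7] before the logarithm.
    """
    p = probabilities if isinstance(probabilities, Tensor) else Tensor(probabilities)
    y = np.asarray(true_labels, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    w = np.ones(y.shape[1]) if class_weights is None else np.asarray(class_weights, dtype=np.float64)
    if (w <= 0).any():
        raise ValueError("class weights must be positive")
    p = p.clip(1e-7, 1.0 - 1e-7)
    terms = Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p + 0.0).log()
    return -(terms * Tensor(w)).mean()


@dataclass
class PredictionResult:
    """Per-peptide output: class probabilities and thresholded labels."""

    id: str
    probabilities: np.ndarray
    labels: np.ndarray


class _Network(_nn.Module):
    """The assembled multi-branch network (branches + fusion head)."""

    def __init__(self, est: "MultiFunctionPeptideClassifier", n_classes: int,
                 smiles_vocab_size: int, kmer_vocab_size: int, rng: np.random.Generator):
        d_total = 0
        if "atomic" in est.branches:
            factory = est.atomic_encoder_factory
            if factory is None:
                encoder = TinyTransformerEncoder(
                    smiles_vocab_size, est.atomic_dim, est.atomic_heads,
                    est.atomic_layers, est.L_atom, rng,
                )
            else:
                encoder = factory(smiles_vocab_size, est.L_atom, rng)
            self.atomic = AtomicBranch(encoder, est.atomic_hidden, est.d_fuse, est.dropout, rng)
            d_total += est.d_fuse
        if "sequence" in est.branches:
            self.sequence = SequenceBranch(
                est.n_positions, est.embed_dim, est.n_heads, est.filters_per_size,
                tuple(est.filter_widths), est.d_fuse, rng,
            )
            d_total += est.d_fuse
        if "hypergraph" in est.branches:
            self.hyper = HyperGATBranch(
                kmer_vocab_size, est.hg_hidden, est.hg_layers, est.d_fuse,
                est.leaky_slope, rng,
            )
            d_total += est.d_fuse
        self.head = FusionHead(d_total, tuple(est.fc_layers), n_classes, est.dropout, rng)


class MultiFunctionPeptideClassifier(ClassifierMixin, BaseEstimator):
    """Multi-granularity multi-label peptide function classifier.

    Parameters mirror the three branches plus training settings; all are
    scikit-learn style constructor arguments, so the estimator works with
    ``get_params`` / ``set_params``, cloning and pipelines.  ``fit`` takes
    a list of peptide sequences (or :class:`PeptideRecord`) and an
    (n_samples, n_classes) binary label matrix.

    Attributes ending in ``_`` are set by :meth:`fit`: ``network_`` (the
    trained network), ``hypergraph_`` (training k-mer hypergraph),
    ``smiles_vocab_``, ``class_weights_``, ``history_`` and ``n_classes_``.
    """

    def __init__(
        self,
        *,
        branches: tuple[str, ...] = ("atomic", "sequence", "hypergraph"),
        n_positions: int = 50,
        embed_dim: int = 192,
        n_heads: int = 8,
        filters_per_size: int = 64,
        filter_widths: tuple[int, ...] = (2, 3, 4, 5),
        L_atom: int = 256,
        atomic_dim: int = 64,
        atomic_heads: int = 4,
        atomic_layers: int = 2,
        atomic_hidden: int = 128,
        atomic_encoder_factory=None,
        k: int = 5,
        hg_hidden: int = 64,
        hg_layers: int = 2,
        leaky_slope: float = 0.2,
        unk_node: bool = True,
        d_fuse: int = 128,
        fc_layers: tuple[int, ...] = (128,),
        dropout: float = 0.25,
        threshold: float = 0.5,
        batch_size: int = 128,
        learning_rate: float = 5e-6,
        epochs: int = 30,
        warmup_fraction: float = 0.1,
        weight_decay: float = 0.01,
        class_weighting: bool = True,
        validation_fraction: float = 0.1,
        verbose: int = 0,
        random_state: int | None = None,
    ):
        self.branches = branches
        self.n_positions = n_positions
        self.embed_dim = embed_dim
        self.n_heads = n_heads
        self.filters_per_size = filters_per_size
        self.filter_widths = filter_widths
        self.L_atom = L_atom
        self.atomic_dim = atomic_dim
        self.atomic_heads = atomic_heads
        self.atomic_layers = atomic_layers
        self.atomic_hidden = atomic_hidden
        self.atomic_encoder_factory = atomic_encoder_factory
        self.k = k
        self.hg_hidden = hg_hidden
        self.hg_layers = hg_layers
        self.leaky_slope = leaky_slope
        self.unk_node = unk_node
        self.d_fuse = d_fuse
        self.fc_layers = fc_layers
        self.dropout = dropout
        self.threshold = threshold
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.warmup_fraction = warmup_fraction
        self.weight_decay = weight_decay
        self.class_weighting = class_weighting
        self.validation_fraction = validation_fraction
        self.verbose = verbose
        self.random_state = random_state

    # -- helpers -------------------------------------------------------------

    @staticmethod
    def _as_records(X, y=None) -> list[PeptideRecord]:
        records = []
        for i, item in enumerate(X):
            if isinstance(item, PeptideRecord):
                rec = item
                if y is not None:
                    rec = PeptideRecord(item.id, item.sequence, np.asarray(y[i]))
            else:
                labels = np.asarray(y[i]) if y is not None else np.zeros(len(LABEL_NAMES), dtype=np.int8)
                rec = PeptideRecord(f"x{i:06d}", str(item), labels)
            records.append(rec)
        return records

    def _validate_branches(self) -> tuple[str, ...]:
        valid = {"atomic", "sequence", "hypergraph"}
        branches = tuple(self.branches)
        if not branches or not set(branches) <= valid:
            raise ValueError(f"branches must be a nonempty subset of {sorted(valid)}")
        return branches

    def _encode_atomic(self, sequences: list[str], vocab: SmilesVocabulary) -> np.ndarray:
        ids = np.zeros((len(sequences), self.L_atom), dtype=np.int64)
        for i, s in enumerate(sequences):
            ids[i] = vocab.encode(tokenize_smiles(peptide_to_smiles(s)), self.L_atom)
        return ids

    # -- fitting --------------------------------------------------------------

    def fit(self, X, y):
        y = np.asarray(y, dtype=np.int8)
        if y.ndim != 2:
            raise ValueError("y must be an (n_samples, n_classes) binary matrix")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("y must be binary")
        if (y.sum(axis=1) == 0).any():
            raise ValueError("every training record needs at least one positive label")
        records = self._as_records(X, y)
        if len(records) < 2:
            raise ValueError("need at least 2 training records")
        branches = self._validate_branches()
        n_classes = y.shape[1]
        master = np.random.default_rng(self.random_state)
        init_rng = np.random.default_rng(master.integers(2**31))
        shuffle_rng = np.random.default_rng(master.integers(2**31))
        drop_rng = np.random.default_rng(master.integers(2**31))

        sequences = [r.sequence for r in records]
        enc: dict[str, np.ndarray] = {}
        smiles_vocab = None
        graph = None
        if "sequence" in branches:
            enc["res"], enc["struct"] = encode_batch(sequences, self.n_positions)
        if "atomic" in branches:
            smiles = [peptide_to_smiles(s) for s in sequences]
            smiles_vocab = SmilesVocabulary.from_sequences(smiles)
            enc["atom"] = np.stack(
                [smiles_vocab.encode(tokenize_smiles(s), self.L_atom) for s in smiles]
            )
        if "hypergraph" in branches:
            graph = build_hypergraph(records, self.k)

        weights = np.ones(n_classes)
        if self.class_weighting:
            counts = np.maximum(y.sum(axis=0), 1)
            weights = len(records) / (n_classes * counts)

        net = _Network(
            self, n_classes,
            smiles_vocab_size=len(smiles_vocab) if smiles_vocab else 0,
            kmer_vocab_size=len(graph.node_vocab) if graph else 0,
            rng=init_rng,
        )

        n = len(records)
        idx_all = shuffle_rng.permutation(n)
        n_val = int(round(self.validation_fraction * n))
        val_idx = np.sort(idx_all[:n_val])
        train_idx = np.sort(idx_all[n_val:])

        steps_per_epoch = int(np.ceil(len(train_idx) / self.batch_size))
        total_steps = max(1, steps_per_epoch * self.epochs)
        opt = _nn.AdamW(
            net.parameters(), lr=self.learning_rate,
            weight_decay=self.weight_decay,
            warmup_steps=int(self.warmup_fraction * total_steps),
        )

        self.branches_ = branches
        self.n_classes_ = n_classes
        self.classes_ = np.arange(n_classes)
        self.network_ = net
        self.smiles_vocab_ = smiles_vocab
        self.hypergraph_ = graph
        self.class_weights_ = weights
        self.history_ = []
        self._drop_rng = drop_rng

        val_records = [records[i] for i in val_idx]
        y_val = y[val_idx] if n_val else None

        for epoch in range(self.epochs):
            order = shuffle_rng.permutation(train_idx)
            losses = []
            for start in range(0, len(order), self.batch_size):
                batch = order[start : start + self.batch_size]
                probs = self._forward_train(enc, graph, batch)
                loss = multilabel_loss(probs, y[batch], weights)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"training diverged (non-finite loss) at epoch {epoch + 1}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            entry = {"epoch": epoch + 1, "loss": float(np.mean(losses))}
            if n_val:
                report = self._evaluate(val_records, y_val)
                entry.update(report.as_dict())
            self.history_.append(entry)
            if self.verbose:
                print(f"[amhf] epoch {entry['epoch']:3d} loss {entry['loss']:.4f}"
                      + (f" val_abs_true {entry.get('absolute_true', float('nan')):.3f}" if n_val else ""),
                      file=sys.stderr)
        self._refresh_node_cache()
        return self

    def _refresh_node_cache(self) -> None:
        if "hypergraph" in self.branches_ and self.hypergraph_ is not None:
            self.node_cache_ = self.network_.hyper.node_feature_cache(self.hypergraph_)
        else:
            self.node_cache_ = None

    def _forward_train(self, enc, graph, batch_idx) -> Tensor:
        feats = []
        net = self.network_
        if "atomic" in self.branches_:
            ids = enc["atom"][batch_idx]
            feats.append(net.atomic(ids, ids != SmilesVocabulary.PAD,
                                    training=True, rng=self._drop_rng))
        if "sequence" in self.branches_:
            feats.append(net.sequence(enc["res"][batch_idx], enc["struct"][batch_idx]))
        if "hypergraph" in self.branches_:
            feats.append(net.hyper(subgraph(graph, batch_idx)))
        return net.head(feats, training=True, rng=self._drop_rng)

    # -- inference -------------------------------------------------------------

    def _forward_eval(self, records: list[PeptideRecord]) -> np.ndarray:
        net = self.network_
        sequences = [r.sequence for r in records]
        feats = []
        if "atomic" in self.branches_:
            ids = self._encode_atomic(sequences, self.smiles_vocab_)
            feats.append(net.atomic(ids, ids != SmilesVocabulary.PAD, training=False))
        if "sequence" in self.branches_:
            res, struct = encode_batch(sequences, self.n_positions)
            feats.append(net.sequence(res, struct))
        if "hypergraph" in self.branches_:
            g = inference_hypergraph(self.hypergraph_, records, unk_node=self.unk_node)
            feats.append(net.hyper.readout_from_cache(g, self.node_cache_))
        return net.head(feats, training=False).data

    def _evaluate(self, records: list[PeptideRecord], y_true: np.ndarray) -> MetricsReport:
        self._refresh_node_cache()  # parameters moved since the last eval
        probs = self._forward_eval(records)
        return multilabel_metrics(y_true, (probs >= self.threshold).astype(np.int8))

    def predict_proba(self, X, batch_size: int = 256) -> np.ndarray:
        if not hasattr(self, "network_"):
            raise RuntimeError("classifier is not fitted")
        records = self._as_records(X)
        out = []
        for start in range(0, len(records), batch_size):
            out.append(self._forward_eval(records[start : start + batch_size]))
        return np.concatenate(out) if out else np.zeros((0, self.n_classes_))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(np.int8)

    # -- persistence -----------------------------------------------------------

    def save(self, path) -> None:
        """Serialize parameters, vocabularies and config to an .npz archive."""
        if not hasattr(self, "network_"):
            raise RuntimeError("classifier is not fitted")
        params = self.get_params()
        params.pop("atomic_encoder_factory", None)
        meta = {
            "params": {k: (list(v) if isinstance(v, tuple) else v) for k, v in params.items()},
            "n_classes": self.n_classes_,
            "branches": list(self.branches_),
        }
        arrays = {f"param:{k}": v for k, v in self.network_.state_dict().items()}
        if self.smiles_vocab_ is not None:
            arrays["smiles_vocab"] = np.array(self.smiles_vocab_.tokens)
        if self.hypergraph_ is not None:
            g = self.hypergraph_
            arrays["hg_vocab"] = np.array(g.node_vocab)
            arrays["hg_idf"] = g.idf
            arrays["hg_df"] = g.df
            arrays["hg_n_edges"] = np.array([g.n_edges])
            arrays["hg_k"] = np.array([g.k])
            arrays["hg_node_cache"] = self.node_cache_
        arrays["class_weights"] = self.class_weights_
        arrays["meta"] = np.array([json.dumps(meta)])
        with open(path, "wb") as fh:  # keep the exact filename (no .npz suffixing)
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path) -> "MultiFunctionPeptideClassifier":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"][0]))
        params = {
            k: (tuple(v) if isinstance(v, list) else v) for k, v in meta["params"].items()
        }
        est = cls(**params)
        est.branches_ = tuple(meta["branches"])
        est.n_classes_ = int(meta["n_classes"])
        est.classes_ = np.arange(est.n_classes_)
        est.class_weights_ = data["class_weights"]
        est.history_ = []
        est._drop_rng = np.random.default_rng(0)
        smiles_vocab = None
        if "smiles_vocab" in data:
            smiles_vocab = SmilesVocabulary([])
            smiles_vocab.tokens = [str(t) for t in data["smiles_vocab"]]
            smiles_vocab._index = {t: i for i, t in enumerate(smiles_vocab.tokens)}
        est.smiles_vocab_ = smiles_vocab
        graph = None
        if "hg_vocab" in data:
            vocab = [str(t) for t in data["hg_vocab"]]
            empty = np.zeros(0, dtype=np.int64)
            graph = Hypergraph(
                node_vocab=vocab, n_edges=int(data["hg_n_edges"][0]),
                edge_ids=empty, node_ids=empty, tf=np.zeros(0), weight=np.zeros(0),
                node_global=np.arange(len(vocab), dtype=np.int64),
                df=data["hg_df"], idf=data["hg_idf"], k=int(data["hg_k"][0]),
            )
        est.hypergraph_ = graph
        est.node_cache_ = data["hg_node_cache"] if "hg_node_cache" in data else None
        net = _Network(
            est, est.n_classes_,
            smiles_vocab_size=len(smiles_vocab) if smiles_vocab else 0,
            kmer_vocab_size=len(graph.node_vocab) if graph else 0,
            rng=np.random.default_rng(0),
        )
        net.load_state_dict({k[6:]: data[k] for k in data.files if k.startswith("param:")})
        est.network_ = net
        return est


def train_model(train_records: list[PeptideRecord], config: dict | None = None,
                seed: int = 0) -> tuple[MultiFunctionPeptideClassifier, list[dict]]:
    """Fit a classifier on labeled records; returns (model, per-epoch history)."""
    config = dict(config or {})
    config.setdefault("random_state", seed)
    clf = MultiFunctionPeptideClassifier(**config)
    y = np.stack([r.labels for r in train_records])
    clf.fit(train_records, y)
    return clf, clf.history_


def predict_records(
    model: MultiFunctionPeptideClassifier, records: list[PeptideRecord]
) -> tuple[list[PredictionResult], list[tuple[str, str]]]:
    """Predict for records, skipping (and reporting) ones too short for k-mers.

    Returns (results, errors) where errors is a list of (record id, reason).
    """
    errors: list[tuple[str, str]] = []
    usable: list[PeptideRecord] = []
    need_k = "hypergraph" in model.branches_
    for rec in records:
        if need_k and len(rec.sequence) < model.k:
            errors.append((rec.id, f"sequence shorter than k={model.k}"))
        else:
            usable.append(rec)
    results: list[PredictionResult] = []
    if usable:
        probs = model.predict_proba(usable)
        labels = (probs >= model.threshold).astype(np.int8)
        for rec, p, lab in zip(usable, probs, labels):
            results.append(PredictionResult(rec.id, p, lab))
    return results, errors


def tiny_classifier(**overrides) -> MultiFunctionPeptideClassifier:
    """A small random-init configuration that trains in minutes on one CPU.

    Keeps the architecture (all three branches, MHSA + TextCNN, 2-layer
    HyperGAT, concatenation fusion) at reduced widths: embedding 32,
    4 heads, 16 filters per width, fuse dimension 32, SMILES truncated at
    64 tokens.  The learning rate (2e-3) is the usual Adam scale for small
    networks trained from scratch.
    """
    params = dict(
        embed_dim=32, n_heads=4, filters_per_size=16,
        L_atom=64, atomic_dim=16, atomic_heads=2, atomic_layers=1, atomic_hidden=32,
        hg_hidden=32, hg_layers=2, d_fuse=32, fc_layers=(64,), dropout=0.1,
        batch_size=128, learning_rate=2e-3, epochs=30, warmup_fraction=0.1,
        weight_decay=0.01, validation_fraction=0.0,
    )
    params.update(overrides)
    return MultiFunctionPeptideClassifier(**params)
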