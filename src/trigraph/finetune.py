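"""Scaffold splits, supervised heads on the encoder, and evaluation metrics.

Downstream tasks attach a two-layer perceptron to the pooled molecule
vector (molecule-level regression / binary classification) or to the final
per-atom states (atom-level regression, e.g. partial charges) and train the
head and encoder end-to-end.  Datasets are partitioned by Bemis-Murcko
scaffold so the test set probes out-of-scaffold generalisation, and every
reported score is the mean +/- sd over independent repeats with distinct
seeds.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.metrics import mean_absolute_error, mean_squared_error, roc_auc_score

from . import nn
from .molgraph import FeatureConfig, Molecule
from .network import NetworkConfig, TriGraphEncoder, make_batch
from .nn import Tensor, bce_logits
from .ssl import EncodedMolecule, encode_dataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Scaffold split

@dataclass
class ScaffoldSplit:
    train: list[str]
    valid: list[str]
    test: list[str]
    fractions: tuple[float, float, float]
    scaffold_to_ids: dict[str, list[str]]


def _scaffold_smiles(mol: Molecule, generic: bool = False) -> str:
    if mol.rdmol is None:
        raise ValueError(f"{mol.id}: structure required for scaffold")
    core = MurckoScaffold.GetScaffoldForMol(mol.rdmol)
    if generic:
        core = MurckoScaffold.MakeScaffoldGeneric(core)
    return Chem.MolToSmiles(core)


def scaffold_split(mols: list[Molecule],
                   fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                   generic: bool = False) -> ScaffoldSplit:
    """Greedy deterministic Bemis-Murcko scaffold partition.

    Scaffold groups, sorted by descending size then scaffold string, are
    assigned whole to train until the train fraction is reached, then to
    valid, then test; molecules sharing a scaffold never straddle
    partitions.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    groups: dict[str, list[str]] = {}
    for m in mols:
        groups.setdefault(_scaffold_smiles(m, generic), []).append(m.id)
    if len(groups) < 3:
        raise ValueError(
            f"only {len(groups)} distinct scaffolds; use a random split instead")
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    n = len(mols)
    n_train, n_valid = fractions[0] * n, (fractions[0] + fractions[1]) * n
    train, valid, test = [], [], []
    for _, ids in ordered:
        if len(train) + len(ids) <= n_train or not train:
            train.extend(ids)
        elif len(train) + len(valid) + len(ids) <= n_valid or not valid:
            valid.extend(ids)
        else:
            test.extend(ids)
    if not test:  # degenerate granularity: move the last valid group over
        test, valid = valid, test
    return ScaffoldSplit(train, valid, test, tuple(fractions), groups)


# ---------------------------------------------------------------------------
# Tasks and metrics

@dataclass
class TaskSpec:
    kind: str                 # "classification" | "regression" | "atom_regression"
    metric: str               # "roc_auc" | "rmse" | "mae"
    repeats: int = 4

    def __post_init__(self):
        allowed = {"classification": {"roc_auc"},
                   "regression": {"rmse", "mae"},
                   "atom_regression": {"rmse", "mae"}}
        if self.kind not in allowed:
            raise ValueError(f"unknown task kind {self.kind!r}")
        if self.metric not in allowed[self.kind]:
            raise ValueError(f"metric {self.metric!r} invalid for {self.kind}")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def evaluate(predictions: np.ndarray, labels: np.ndarray, metric: str) -> float:
    """ROC-AUC (rank statistic), RMSE or MAE.

    2D arrays are treated as multi-task: the mean is taken over columns, and
    for ROC-AUC only columns with both a positive and a negative label count
    (degenerate columns are excluded).
    """
    pred = np.asarray(predictions, dtype=float)
    lab = np.asarray(labels, dtype=float)
    if pred.shape != lab.shape:
        raise ValueError("prediction/label shape mismatch")
    if pred.ndim == 2:
        scores = []
        for c in range(pred.shape[1]):
            keep = ~np.isnan(lab[:, c])
            if metric == "roc_auc" and len(np.unique(lab[keep, c])) < 2:
                continue
            scores.append(evaluate(pred[keep, c], lab[keep, c], metric))
        if not scores:
            raise ValueError("no evaluable task columns")
        return float(np.mean(scores))
    if metric == "roc_auc":
        if len(np.unique(lab)) < 2:
            raise ValueError("ROC-AUC needs both classes present")
        return float(roc_auc_score(lab, pred))
    if metric == "rmse":
        return float(np.sqrt(mean_squared_error(lab, pred)))
    if metric == "mae":
        return float(mean_absolute_error(lab, pred))
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# Head fitting

@dataclass
class FinetuneConfig:
    lr: float = 1e-3
    epochs: int = 100
    patience: int = 10        # early stopping on the validation metric
    batch_size: int = 32
    seed: int = 0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)


@dataclass
class FitResult:
    test_scores: list[float]  # one per repeat
    mean: float
    sd: float
    metric: str
    predictions: dict[str, np.ndarray]  # test-set predictions, last repeat


class _HeadModel(nn.Module):
    def __init__(self, encoder: TriGraphEncoder, seed: int):
        self.encoder = encoder
        rng = np.random.default_rng(seed + 15485863)
        self.head = nn.MLP(encoder.config.hidden, encoder.config.hidden, 1, rng)

    def __call__(self, batch, atom_level: bool, rng=None) -> Tensor:
        h_atom, _, _ = self.encoder.forward_states(batch, rng)
        if atom_level:
            return self.head(h_atom).reshape(-1)
        return self.head(self.encoder.readout(h_atom, batch)).reshape(-1)


def _metric_direction(metric: str) -> float:
    return 1.0 if metric == "roc_auc" else -1.0


def fit_head(encoded: dict[str, EncodedMolecule], labels: dict[str, np.ndarray],
             task: TaskSpec, split: ScaffoldSplit,
             config: FinetuneConfig | None = None,
             init_model: TriGraphEncoder | None = None) -> FitResult:
    """Train a prediction head (and the encoder) end-to-end on a scaffold split.

    ``encoded`` maps molecule id -> EncodedMolecule; ``labels`` maps id to a
    scalar (molecule tasks) or a per-atom vector (atom_regression).  For
    each of ``task.repeats`` seeds the checkpoint with the best validation
    metric is selected; the test metric's mean and sd over repeats are
    reported.  NaN labels are dropped with a warning.
    """
    cfg = config or FinetuneConfig()
    atom_level = task.kind == "atom_regression"

    def usable(ids):
        out = []
        for i in ids:
            y = labels.get(i)
            if y is None or np.any(np.isnan(y)):
                logger.warning("dropping %s: missing/NaN label", i)
                continue
            out.append(i)
        return out

    train_ids, valid_ids, test_ids = (usable(split.train), usable(split.valid),
                                      usable(split.test))
    if task.kind == "classification":
        if len({float(labels[i]) for i in train_ids}) < 2:
            raise ValueError("training labels contain a single class")

    def make_xy(ids):
        batch = make_batch([(encoded[i].graph, encoded[i].feats) for i in ids])
        if atom_level:
            y = np.concatenate([np.asarray(labels[i], dtype=float) for i in ids])
        else:
            y = np.array([float(labels[i]) for i in ids])
        return batch, y

    valid_batch, y_valid = make_xy(valid_ids)
    test_batch, y_test = make_xy(test_ids)
    direction = _metric_direction(task.metric)

    test_scores, last_preds = [], None
    for rep in range(task.repeats):
        seed = cfg.seed + 7 * rep
        enc = copy.deepcopy(init_model) if init_model is not None else None
        if enc is None:
            dims = next(iter(encoded.values())).feats.dims
            enc = TriGraphEncoder(dims, replace(cfg.network, seed=seed))
        model = _HeadModel(enc, seed)
        params = model.parameters()
        opt = nn.Adam(params, lr=cfg.lr)
        order_rng = np.random.default_rng(seed + 1)
        drop_rng = np.random.default_rng(seed + 2)

        best = -np.inf
        best_state = [p.data.copy() for p in params]
        stale = 0
        for _epoch in range(cfg.epochs):
            order = order_rng.permutation(len(train_ids))
            for start in range(0, len(order), cfg.batch_size):
                ids = [train_ids[i] for i in order[start:start + cfg.batch_size]]
                batch, y = make_xy(ids)
                pred = model(batch, atom_level, drop_rng)
                if task.kind == "classification":
                    loss = bce_logits(pred, y)
                else:
                    diff = pred - Tensor(y)
                    loss = (diff * diff).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
            val_pred = model(valid_batch, atom_level).data
            try:
                score = direction * evaluate(val_pred, y_valid, task.metric)
            except ValueError:
                # single-class validation labels: select on validation loss
                score = -bce_logits(Tensor(val_pred), y_valid).item()
            if score > best + 1e-12:
                best, stale = score, 0
                best_state = [p.data.copy() for p in params]
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
        for p, s in zip(params, best_state):
            p.data = s
        test_pred = model(test_batch, atom_level).data
        test_scores.append(evaluate(test_pred, y_test, task.metric))
        last_preds = {"ids": np.array(test_ids), "y_pred": test_pred, "y_true": y_test}

    return FitResult(
        test_scores=test_scores,
        mean=float(np.mean(test_scores)),
        sd=float(np.std(test_scores, ddof=1)) if len(test_scores) > 1 else 0.0,
        metric=task.metric,
        predictions=last_preds,
    )


def encode_for_finetune(mols: list[Molecule], features: FeatureConfig | None = None
                        ) -> dict[str, EncodedMolecule]:
    return {e.mol.id: e for e in encode_dataset(mols, features)}
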