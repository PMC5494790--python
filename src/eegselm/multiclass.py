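"""Three-class classification from binary SELMs.

Five combination strategies are supported:

* ``OAA``  (one-against-all): one classifier per class (that class coded
  +1, the rest -1); predict the class with the largest raw decision value.
* ``OAO``  (one-against-one): one classifier per unordered pair, trained
  only on that pair's samples; majority vote, and a 1-1-1 three-way tie is
  resolved by the pairwise classifier with the largest absolute decision
  value.  (With three classes and three votes no other tie can occur.)
* ``DAG``: trained like OAO; prediction walks a rooted directed acyclic
  graph, eliminating the losing class of each pairwise decision — exactly
  two evaluations for three classes.  The root pair is configurable.
* ``ECOC`` (error-correcting output codes): trained like OAA; the sign
  vector of the three outputs is matched to the target codes (1,-1,-1),
  (-1,1,-1), (-1,-1,1) by minimum Hamming distance.
* ``BT``   (binary tree): two classifiers — the root class against the
  rest, then the remaining pair.  The root class is configurable.

All tie-breaks not otherwise specified resolve to the lowest class index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .features import FeatureVector
from .io_synth import CLASS_LABELS
from .selm import (
    BinarySELMModel,
    KernelSpec,
    UpdateMode,
    decision_values,
    model_from_json,
    model_to_json,
    train_binary,
)

__all__ = [
    "STRATEGIES",
    "MulticlassModel",
    "train_multiclass",
    "predict",
    "predict_batch",
    "predict_oaa",
    "predict_oao",
    "predict_dag",
    "predict_ecoc",
    "predict_bt",
    "multiclass_to_json",
    "multiclass_from_json",
]

STRATEGIES = ("OAA", "OAO", "DAG", "ECOC", "BT")


@dataclass(frozen=True)
class MulticlassModel:
    """Binary SELMs plus the combination strategy that wires them.

    ``binary_models`` is keyed by class label for OAA/ECOC, by the label
    pair ``"p|q"`` (first class coded +1) for OAO/DAG, and by ``"root"`` /
    ``"pair"`` for BT.  ``structure`` holds the DAG root pair or the BT
    root class.
    """

    strategy: str
    class_list: tuple[str, ...]
    binary_models: Mapping[str, BinarySELMModel]
    structure: tuple[str, ...] | str | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        expected = 2 if self.strategy == "BT" else len(self.class_list)
        if len(self.binary_models) != expected:
            raise ValueError(
                f"{self.strategy} with {len(self.class_list)} classes needs "
                f"{expected} binary models, got {len(self.binary_models)}"
            )


def _as_arrays(
    dataset: Sequence[FeatureVector] | tuple[np.ndarray, Sequence[str]],
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dataset, tuple):
        X, y = dataset
        return np.atleast_2d(np.asarray(X, dtype=float)), np.asarray(y, dtype=object)
    X = np.array([fv.values for fv in dataset], dtype=float)
    y = np.array([fv.label for fv in dataset], dtype=object)
    return X, y


def _pairs(class_list: Sequence[str]) -> list[tuple[str, str]]:
    return [
        (class_list[i], class_list[j])
        for i in range(len(class_list))
        for j in range(i + 1, len(class_list))
    ]


def train_multiclass(
    dataset: Sequence[FeatureVector] | tuple[np.ndarray, Sequence[str]],
    strategy: str = "OAO",
    class_list: Sequence[str] = CLASS_LABELS,
    structure: tuple[str, str] | str | None = None,
    C: float = 5.0,
    epsilon: float = 1e-3,
    kernel: KernelSpec = KernelSpec.gaussian(500.0),
    max_iter: int | None = None,
    mode: UpdateMode = "newton",
) -> MulticlassModel:
    """Train the binary SELMs required by ``strategy``.

    OAA/ECOC train one one-vs-rest model per class on all samples;
    OAO/DAG train one model per class pair on that pair's samples only;
    BT trains the root class against the rest, then the remaining pair.
    ``structure`` is the DAG root pair (default: first and last class,
    ``("A", "E")``) or the BT root class (default: the last class, ``"E"``,
    the most separable one).
    """
    X, y = _as_arrays(dataset)
    class_list = tuple(class_list)
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}")
    present = set(np.unique(y))
    missing = [c for c in class_list if c not in present]
    if missing:
        raise ValueError(f"dataset is missing class(es) {missing}")

    kw = dict(C=C, epsilon=epsilon, kernel=kernel, max_iter=max_iter, mode=mode)
    models: dict[str, BinarySELMModel] = {}

    if strategy in ("OAA", "ECOC"):
        for cls in class_list:
            t = np.where(y == cls, 1.0, -1.0)
            models[cls] = train_binary(X, t, positive_label=cls, negative_label="rest", **kw)
        structure = None
    elif strategy in ("OAO", "DAG"):
        for p, q in _pairs(class_list):
            mask = (y == p) | (y == q)
            t = np.where(y[mask] == p, 1.0, -1.0)
            models[f"{p}|{q}"] = train_binary(
                X[mask], t, positive_label=p, negative_label=q, **kw
            )
        if strategy == "DAG":
            structure = tuple(structure) if structure else (class_list[0], class_list[-1])
            if len(set(structure)) != 2 or not set(structure) <= set(class_list):
                raise ValueError(f"DAG root pair {structure} must be two distinct classes")
        else:
            structure = None
    else:  # BT
        root = str(structure) if structure else class_list[-1]
        if root not in class_list:
            raise ValueError(f"BT root class {root!r} not in class_list")
        rest = [c for c in class_list if c != root]
        t_root = np.where(y == root, 1.0, -1.0)
        models["root"] = train_binary(X, t_root, positive_label=root, negative_label="rest", **kw)
        mask = (y == rest[0]) | (y == rest[1])
        t_pair = np.where(y[mask] == rest[0], 1.0, -1.0)
        models["pair"] = train_binary(
            X[mask], t_pair, positive_label=rest[0], negative_label=rest[1], **kw
        )
        structure = root

    return MulticlassModel(
        strategy=strategy, class_list=class_list, binary_models=dict(models), structure=structure
    )


def _row(x: np.ndarray) -> np.ndarray:
    return np.asarray(x, dtype=float).reshape(1, -1)


def predict_oaa(model: MulticlassModel, x: np.ndarray) -> str:
    """Class with the largest raw one-vs-rest decision value (argmax)."""
    values = [decision_values(model.binary_models[c], _row(x))[0] for c in model.class_list]
    return model.class_list[int(np.argmax(values))]


def predict_oao(model: MulticlassModel, x: np.ndarray) -> str:
    """Pairwise majority vote; a 1-1-1 tie defers to the largest |f|."""
    votes = {c: 0 for c in model.class_list}
    fvals: dict[tuple[str, str], float] = {}
    for p, q in _pairs(model.class_list):
        f = decision_values(model.binary_models[f"{p}|{q}"], _row(x))[0]
        fvals[(p, q)] = f
        votes[p if f >= 0 else q] += 1
    best = max(votes.values())
    winners = [c for c in model.class_list if votes[c] == best]
    if len(winners) == 1:
        return winners[0]
    # with 3 classes and 3 votes the only possible tie is 1-1-1
    assert len(winners) == len(model.class_list), "unexpected partial vote tie"
    (p, q), f = max(fvals.items(), key=lambda item: abs(item[1]))
    return p if f >= 0 else q


def predict_dag(model: MulticlassModel, x: np.ndarray) -> str:
    """Sequential pairwise elimination from the root pair; 2 evaluations."""
    survivors = list(model.class_list)
    p, q = model.structure  # type: ignore[misc]
    while len(survivors) > 1:
        key = f"{p}|{q}" if f"{p}|{q}" in model.binary_models else f"{q}|{p}"
        f = decision_values(model.binary_models[key], _row(x))[0]
        pos = model.binary_models[key].positive_label
        neg = model.binary_models[key].negative_label
        loser = neg if f >= 0 else pos
        survivors.remove(loser)
        if len(survivors) > 1:
            p, q = survivors[0], survivors[1]
    return survivors[0]


_ECOC_CODES = {0: (1, -1, -1), 1: (-1, 1, -1), 2: (-1, -1, 1)}


def predict_ecoc(model: MulticlassModel, x: np.ndarray) -> str:
    """Nearest target code in Hamming distance; ties to the lowest index."""
    signs = tuple(
        1 if decision_values(model.binary_models[c], _row(x))[0] >= 0 else -1
        for c in model.class_list
    )
    dists = [
        sum(s != c for s, c in zip(signs, _ECOC_CODES[i]))
        for i in range(len(model.class_list))
    ]
    return model.class_list[int(np.argmin(dists))]


def predict_bt(model: MulticlassModel, x: np.ndarray) -> str:
    """Root class vs rest, then the remaining pair (at most 2 evaluations)."""
    root_model = model.binary_models["root"]
    if decision_values(root_model, _row(x))[0] >= 0:
        return root_model.positive_label  # type: ignore[return-value]
    pair_model = model.binary_models["pair"]
    f = decision_values(pair_model, _row(x))[0]
    return pair_model.positive_label if f >= 0 else pair_model.negative_label  # type: ignore[return-value]


_PREDICTORS = {
    "OAA": predict_oaa,
    "OAO": predict_oao,
    "DAG": predict_dag,
    "ECOC": predict_ecoc,
    "BT": predict_bt,
}


def predict(model: MulticlassModel, x: np.ndarray) -> str:
    """Predict the class of one feature vector per the model's strategy."""
    return _PREDICTORS[model.strategy](model, x)


def predict_batch(model: MulticlassModel, X: np.ndarray) -> np.ndarray:
    """Predict classes for each row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.array([predict(model, row) for row in X], dtype=object)


def multiclass_to_json(model: MulticlassModel) -> str:
    """Serialise strategy, structure and embedded binary models to JSON."""
    return json.dumps(
        {
            "strategy": model.strategy,
            "class_list": list(model.class_list),
            "structure": list(model.structure)
            if isinstance(model.structure, tuple)
            else model.structure,
            "binary_models": {k: json.loads(model_to_json(m)) for k, m in model.binary_models.items()},
        }
    )


def multiclass_from_json(text: str) -> MulticlassModel:
    payload = json.loads(text)
    structure = payload["structure"]
    if isinstance(structure, list):
        structure = tuple(structure)
    return MulticlassModel(
        strategy=payload["strategy"],
        class_list=tuple(payload["class_list"]),
        binary_models={
            k: model_from_json(json.dumps(m)) for k, m in payload["binary_models"].items()
        },
        structure=structure,
    )
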