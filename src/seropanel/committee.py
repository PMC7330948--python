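"""Committee-vote feedforward neural-network classifier.

The classifier is an ensemble of small fully connected networks (default
7 inputs - 5 hidden - 2 softmax outputs, the hidden size given by the
sizing rule Nh = (4n^2 + 3)/(n^2 - 8) rounded to the nearest integer).
For each of ``n_repeats`` independent random fold plans, one network is
trained per fold on the 90% training portion by full-batch gradient
backpropagation on the cross-entropy loss, with the held-out 10%
verification portion used only for early stopping. With 10 folds and 50
repeats the committee holds 500 member networks. A sample's committee
vote is the arithmetic mean of all members' HCC-node probabilities, and
classification calls HCC iff the vote strictly exceeds the threshold
(default 0.5; ties go to control).

The model/results split follows the usual statistical-modelling idiom:
:class:`CommitteeANN` holds data and configuration, ``fit`` returns a
:class:`CommitteeANNResults` carrying the trained members, in-sample and
out-of-fold votes, prediction with a train/blind leakage guard, a summary
table, and lossless JSON serialization.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from ._utils import Standardizer, spawn_seed, substream
from .errors import LeakageError, ValidationError

logger = logging.getLogger(__name__)


def hidden_size_rule(n_inputs: int) -> int:
    """Hidden-layer size Nh = (4n^2 + 3)/(n^2 - 8), rounded half-up.

    Defined for n_inputs >= 3 (the denominator must be positive); n = 7
    gives 199/41 ~= 4.854 -> 5.
    """
    n = int(n_inputs)
    if n <= 2:
        raise ValidationError("hidden_size_rule requires n_inputs >= 3 (n^2 - 8 must be positive)")
    value = (4.0 * n * n + 3.0) / (n * n - 8.0)
    return int(math.floor(value + 0.5))


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture and training hyper-parameters of one member network."""

    n_inputs: int
    n_hidden: int | None = None
    n_outputs: int = 2
    hidden_activation: str = "logistic"
    learning_rate: float = 0.05
    max_epochs: int = 500
    early_stop_patience: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_inputs < 1:
            raise ValidationError("n_inputs must be >= 1")
        if self.n_outputs != 2:
            raise ValidationError("the committee network has exactly 2 output nodes")
        if self.hidden_activation not in ("logistic", "tanh"):
            raise ValidationError("hidden_activation must be 'logistic' or 'tanh'")
        if self.n_hidden is not None and self.n_hidden < 1:
            raise ValidationError("n_hidden must be >= 1")

    @property
    def hidden(self) -> int:
        return self.n_hidden if self.n_hidden is not None else hidden_size_rule(self.n_inputs)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


class FeedForwardNet:
    """A small two-layer softmax network trained by backpropagation."""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        rng = substream(spec.seed, 23)
        h, d = spec.hidden, spec.n_inputs
        self.W1 = rng.normal(0.0, 1.0 / math.sqrt(d), size=(d, h))
        self.b1 = np.zeros(h)
        self.W2 = rng.normal(0.0, 1.0 / math.sqrt(h), size=(h, 2))
        self.b2 = np.zeros(2)

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        z = X @ self.W1 + self.b1
        return _sigmoid(z) if self.spec.hidden_activation == "logistic" else np.tanh(z)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability assigned to the HCC output node (class 1)."""
        a = self._hidden(np.asarray(X, dtype=float))
        return _softmax(a @ self.W2 + self.b2)[:, 1]

    def _loss(self, X: np.ndarray, y01: np.ndarray) -> float:
        p = np.clip(self.predict_proba(X), 1e-12, 1 - 1e-12)
        return float(-np.mean(y01 * np.log(p) + (1 - y01) * np.log(1 - p)))

    def fit(self, X, y, X_val=None, y_val=None) -> "FeedForwardNet":
        """Full-batch gradient descent with verification-set early stopping.

        The verification data never contribute to weight updates; they only
        decide when to stop and which epoch's weights to keep.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(np.unique(y)) < 2:
            raise ValidationError("training set contains a single class")
        Y = np.column_stack([1 - y, y])
        lr = self.spec.learning_rate
        n = X.shape[0]
        use_val = X_val is not None and len(X_val) > 0
        if use_val:
            X_val = np.asarray(X_val, dtype=float)
            y_val = np.asarray(y_val, dtype=float)
        best = (np.inf, None)
        patience_left = self.spec.early_stop_patience
        for _ in range(self.spec.max_epochs):
            A = self._hidden(X)
            P = _softmax(A @ self.W2 + self.b2)
            dZ2 = (P - Y) / n
            gW2 = A.T @ dZ2
            gb2 = dZ2.sum(axis=0)
            dA = dZ2 @ self.W2.T
            if self.spec.hidden_activation == "logistic":
                dZ1 = dA * A * (1.0 - A)
            else:
                dZ1 = dA * (1.0 - A**2)
            gW1 = X.T @ dZ1
            gb1 = dZ1.sum(axis=0)
            self.W1 -= lr * gW1
            self.b1 -= lr * gb1
            self.W2 -= lr * gW2
            self.b2 -= lr * gb2
            if use_val:
                val_loss = self._loss(X_val, y_val)
                if val_loss < best[0] - 1e-12:
                    best = (val_loss, self._weights())
                    patience_left = self.spec.early_stop_patience
                else:
                    patience_left -= 1
                    if patience_left <= 0:
                        break
        if use_val and best[1] is not None:
            self._set_weights(best[1])
        return self

    def _weights(self):
        return [self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy()]

    def _set_weights(self, w):
        self.W1, self.b1, self.W2, self.b2 = (a.copy() for a in w)

    def to_dict(self) -> dict:
        return {
            "spec": {
                "n_inputs": self.spec.n_inputs,
                "n_hidden": self.spec.hidden,
                "n_outputs": 2,
                "hidden_activation": self.spec.hidden_activation,
                "learning_rate": self.spec.learning_rate,
                "max_epochs": self.spec.max_epochs,
                "early_stop_patience": self.spec.early_stop_patience,
                "seed": self.spec.seed,
            },
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeedForwardNet":
        net = cls(NetworkSpec(**d["spec"]))
        net.W1 = np.asarray(d["W1"], dtype=float)
        net.b1 = np.asarray(d["b1"], dtype=float)
        net.W2 = np.asarray(d["W2"], dtype=float)
        net.b2 = np.asarray(d["b2"], dtype=float)
        return net


def train_network(train_values, train_labels, spec: NetworkSpec, val_values=None, val_labels=None):
    """Train one member network (values are assumed already standardized)."""
    return FeedForwardNet(spec).fit(train_values, train_labels, val_values, val_labels)


def committee_fold_plans(n_samples: int, n_folds: int, n_repeats: int, seed: int):
    """The repeated random fold plans behind a committee, one per repeat.

    Yields ``n_repeats`` lists of (train_idx, verification_idx) pairs;
    the committee trains exactly one network per pair, hence
    ``n_folds * n_repeats`` networks in total.
    """
    plans = []
    for repeat in range(n_repeats):
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=spawn_seed(seed, 31, repeat))
        plans.append(list(kf.split(np.arange(n_samples))))
    return plans


def committee_vote(members, sample_values) -> np.ndarray:
    """Arithmetic mean of all member networks' HCC-node outputs."""
    X = np.asarray(sample_values, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    nets = [m if isinstance(m, FeedForwardNet) else m.network for m in members]
    if X.shape[1] != nets[0].spec.n_inputs:
        raise ValidationError(
            f"feature dimension {X.shape[1]} does not match panel size {nets[0].spec.n_inputs}"
        )
    votes = np.mean([net.predict_proba(X) for net in nets], axis=0)
    return votes


def classify(vote, threshold: float = 0.5):
    """HCC iff vote strictly exceeds the threshold; ties -> control."""
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must be in (0, 1)")
    votes = np.asarray(vote, dtype=float)
    if ((votes < 0) | (votes > 1)).any():
        raise ValidationError("votes must lie in [0, 1]")
    labels = np.where(votes > threshold, "HCC", "control")
    return labels if votes.ndim else str(labels)


@dataclass
class CommitteeMember:
    """One trained network with its fold/repeat provenance."""

    repeat: int
    fold: int
    network: FeedForwardNet
    verification_ids: list


class CommitteeANN:
    """Committee model over a marker panel.

    Parameters
    ----------
    endog : array-like of {0, 1}
        Class labels (1 = HCC) of the training-phase samples.
    exog : pandas.DataFrame
        Samples x panel-markers values (raw scale; the model standardizes
        with training-phase mean/SD and freezes those parameters).
    spec : NetworkSpec, optional
        Member architecture; defaults to the sizing rule on the panel width.
    """

    def __init__(self, endog, exog: pd.DataFrame, spec: NetworkSpec | None = None,
                 n_folds: int = 10, n_repeats: int = 50, vote_threshold: float = 0.5):
        self.exog = pd.DataFrame(exog)
        self.endog = np.asarray(endog, dtype=float)
        if self.endog.shape[0] != self.exog.shape[0]:
            raise ValidationError("endog/exog length mismatch")
        if self.exog.shape[0] < n_folds:
            raise ValidationError("need at least n_folds samples")
        if len(np.unique(self.endog)) < 2:
            raise ValidationError("both classes must be present")
        if not 0.0 < vote_threshold < 1.0:
            raise ValidationError("vote_threshold must be in (0, 1)")
        self.spec = spec or NetworkSpec(n_inputs=self.exog.shape[1])
        if self.spec.n_inputs != self.exog.shape[1]:
            raise ValidationError("spec.n_inputs must equal the panel width")
        self.n_folds = n_folds
        self.n_repeats = n_repeats
        self.vote_threshold = vote_threshold

    def fit(self, seed: int = 0, max_redraws: int = 100) -> "CommitteeANNResults":
        """Train n_folds x n_repeats member networks.

        A repeat whose fold plan leaves any training or verification fold
        single-class is re-drawn (logged), so every member sees both
        classes.
        """
        std = Standardizer.fit(self.exog)
        Z = std.transform(self.exog).to_numpy(dtype=float)
        y = self.endog
        ids = list(self.exog.index)
        members: list[CommitteeMember] = []
        oof_sum = np.zeros(len(y))
        oof_count = np.zeros(len(y))
        for repeat in range(self.n_repeats):
            plan = None
            for attempt in range(max_redraws):
                kf = KFold(
                    n_splits=self.n_folds,
                    shuffle=True,
                    random_state=spawn_seed(seed, 31, repeat, attempt),
                )
                candidate = list(kf.split(Z))
                ok = all(
                    len(np.unique(y[tr])) == 2 and len(np.unique(y[va])) == 2
                    for tr, va in candidate
                )
                if ok:
                    plan = candidate
                    if attempt:
                        logger.info("repeat %d: fold plan re-drawn %d time(s)", repeat, attempt)
                    break
            if plan is None:
                raise ValidationError("could not draw a fold plan with both classes in every fold")
            for fold, (tr, va) in enumerate(plan):
                net_spec = replace(self.spec, seed=spawn_seed(seed, 37, repeat, fold))
                net = train_network(Z[tr], y[tr], net_spec, Z[va], y[va])
                members.append(
                    CommitteeMember(
                        repeat=repeat,
                        fold=fold,
                        network=net,
                        verification_ids=[ids[i] for i in va],
                    )
                )
                oof_sum[va] += net.predict_proba(Z[va])
                oof_count[va] += 1
        votes = committee_vote(members, Z)
        oof = oof_sum / np.maximum(oof_count, 1)
        return CommitteeANNResults(
            model=self,
            members=members,
            standardizer=std,
            votes=pd.Series(votes, index=self.exog.index, name="vote"),
            oof_votes=pd.Series(oof, index=self.exog.index, name="oof_vote"),
            seed=seed,
        )


@dataclass
class CommitteeANNResults:
    """A fitted committee: members, frozen preprocessing, votes."""

    model: CommitteeANN
    members: list
    standardizer: Standardizer
    votes: pd.Series
    oof_votes: pd.Series
    seed: int

    @property
    def n_networks(self) -> int:
        return len(self.members)

    @property
    def training_ids(self) -> set:
        return set(self.model.exog.index)

    def predict(self, new_values: pd.DataFrame, check_leakage: bool = True) -> pd.Series:
        """Committee votes for new samples with frozen standardization.

        With ``check_leakage`` (the default) any sample ID shared with the
        training phase raises :class:`LeakageError`; a blind validation
        phase must be disjoint from the samples the committee saw.
        """
        new_values = pd.DataFrame(new_values)
        missing = set(self.standardizer.mean.index) - set(new_values.columns)
        if missing:
            raise ValidationError(f"new data lacks panel markers: {sorted(missing)}")
        if check_leakage:
            overlap = self.training_ids & set(new_values.index)
            if overlap:
                raise LeakageError(
                    f"{len(overlap)} sample ID(s) shared with the training phase, "
                    f"e.g. {sorted(overlap)[:3]}"
                )
        Z = self.standardizer.transform(new_values).to_numpy(dtype=float)
        return pd.Series(committee_vote(self.members, Z), index=new_values.index, name="vote")

    def classify(self, votes=None, threshold: float | None = None):
        votes = self.votes if votes is None else votes
        thr = self.model.vote_threshold if threshold is None else threshold
        return pd.Series(classify(np.asarray(votes), thr), index=getattr(votes, "index", None))

    def summary(self) -> str:
        lines = [
            "Committee ANN results",
            "=====================",
            f"panel markers       : {', '.join(self.model.exog.columns)}",
            f"architecture        : {self.model.spec.n_inputs}-{self.model.spec.hidden}-2",
            f"members             : {self.n_networks} "
            f"({self.model.n_folds} folds x {self.model.n_repeats} repeats)",
            f"training samples    : {self.model.exog.shape[0]} "
            f"(HCC {int(self.model.endog.sum())}, control {int((1 - self.model.endog).sum())})",
            f"vote threshold      : {self.model.vote_threshold}",
            f"fit seed            : {self.seed}",
        ]
        try:
            from .evaluate import roc_auc

            is_case = self.model.endog == 1
            lines.append(
                f"in-sample AUC       : "
                f"{roc_auc(self.votes[is_case], self.votes[~is_case]):.3f}"
            )
            lines.append(
                f"out-of-fold AUC     : "
                f"{roc_auc(self.oof_votes[is_case], self.oof_votes[~is_case]):.3f}"
            )
        except Exception:  # pragma: no cover - summary stays printable
            pass
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "format": "seropanel-committee-v1",
            "panel": list(self.model.exog.columns),
            "n_folds": self.model.n_folds,
            "n_repeats": self.model.n_repeats,
            "vote_threshold": self.model.vote_threshold,
            "seed": self.seed,
            "standardizer": self.standardizer.to_dict(),
            "training_ids": sorted(map(str, self.model.exog.index)),
            "members": [
                {
                    "repeat": m.repeat,
                    "fold": m.fold,
                    "verification_ids": list(map(str, m.verification_ids)),
                    "network": m.network.to_dict(),
                }
                for m in self.members
            ],
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
                fh.write("\n")
        return text

    @classmethod
    def from_json(cls, source) -> "FrozenCommittee":
        import os

        if isinstance(source, os.PathLike) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            with open(source) as fh:
                payload = json.load(fh)
        else:
            payload = json.loads(source)
        if payload.get("format") != "seropanel-committee-v1":
            raise ValidationError("not a serialized committee model")
        members = [
            CommitteeMember(
                repeat=m["repeat"],
                fold=m["fold"],
                network=FeedForwardNet.from_dict(m["network"]),
                verification_ids=m["verification_ids"],
            )
            for m in payload["members"]
        ]
        return FrozenCommittee(
            panel=payload["panel"],
            members=members,
            standardizer=Standardizer.from_dict(payload["standardizer"]),
            training_ids=set(payload["training_ids"]),
            vote_threshold=payload["vote_threshold"],
            n_folds=payload["n_folds"],
            n_repeats=payload["n_repeats"],
            seed=payload["seed"],
        )


@dataclass
class FrozenCommittee:
    """A deserialized committee: prediction only, no refitting."""

    panel: list
    members: list
    standardizer: Standardizer
    training_ids: set
    vote_threshold: float
    n_folds: int
    n_repeats: int
    seed: int

    @property
    def n_networks(self) -> int:
        return len(self.members)

    def predict(self, new_values: pd.DataFrame, check_leakage: bool = True) -> pd.Series:
        new_values = pd.DataFrame(new_values)
        missing = set(self.panel) - set(new_values.columns)
        if missing:
            raise ValidationError(f"new data lacks panel markers: {sorted(missing)}")
        if check_leakage:
            overlap = self.training_ids & set(map(str, new_values.index))
            if overlap:
                raise LeakageError(f"{len(overlap)} sample ID(s) shared with the training phase")
        Z = self.standardizer.transform(new_values).to_numpy(dtype=float)
        return pd.Series(committee_vote(self.members, Z), index=new_values.index, name="vote")


def build_committee(
    values: pd.DataFrame,
    labels,
    n_folds: int = 10,
    n_repeats: int = 50,
    spec: NetworkSpec | None = None,
    seed: int = 0,
    vote_threshold: float = 0.5,
) -> CommitteeANNResults:
    """Convenience wrapper: construct and fit a :class:`CommitteeANN`."""
    model = CommitteeANN(
        labels, values, spec=spec, n_folds=n_folds, n_repeats=n_repeats,
        vote_threshold=vote_threshold,
    )
    return model.fit(seed=seed)


def blind_predict(results, new_values: pd.DataFrame, check_leakage: bool = True) -> pd.Series:
    """Votes for a blind phase with frozen preprocessing (no refitting)."""
    return results.predict(new_values, check_leakage=check_leakage)
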