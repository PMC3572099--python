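"""Orient undirected interactions with a categorical naive Bayes classifier.

Interactions of known direction (curated kinase -> substrate edges) form the
training set; every remaining edge is then assigned the maximum-posterior
orientation.  For an ordered pair (a, b) the class ``forward`` means a -> b.

The default feature schema for an ordered pair:

* ``rel_degree``  - degree of a vs b (``gt`` / ``lt`` / ``eq``)
* ``a_kinase`` / ``b_kinase`` - endpoint kinase flags
* ``a_ptm`` / ``b_ptm`` - endpoint PTM-site count, binned into terciles
  computed on the training set

The schema is pluggable: any mapping feature-name -> category works, as long
as training and prediction share it.  Categories never seen in training map
to a reserved ``unknown`` level that received Laplace mass.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .model import AnnotatedNetwork, Interaction

__all__ = [
    "FORWARD",
    "REVERSE",
    "FeatureExtractor",
    "NaiveBayesModel",
    "train_naive_bayes",
    "predict_direction",
    "orient_network",
]

FORWARD = "forward"
REVERSE = "reverse"
UNKNOWN = "__unknown__"


class FeatureExtractor:
    """Compute the default feature vector for an ordered node pair.

    PTM-count bin edges are terciles of the per-node PTM counts seen among
    training endpoints; call :meth:`fit_bins` before extracting.
    """

    def __init__(self):
        self.ptm_edges: tuple[float, float] = (0.0, 2.0)
        self._degree: dict[str, int] = {}
        self._fitted = False

    def fit(self, net: AnnotatedNetwork, training_nodes=None) -> "FeatureExtractor":
        self._degree = {pid: len(net.neighbors(pid)) for pid in net.proteins}
        nodes = list(training_nodes) if training_nodes is not None else list(net.proteins)
        counts = np.array([len(net.proteins[p].ptms) for p in nodes], dtype=float)
        if counts.size:
            self.ptm_edges = (float(np.quantile(counts, 1 / 3)), float(np.quantile(counts, 2 / 3)))
        self._net = net
        self._fitted = True
        return self

    def _ptm_bin(self, count: int) -> str:
        lo, hi = self.ptm_edges
        if count <= lo:
            return "low"
        if count <= hi:
            return "mid"
        return "high"

    def __call__(self, a: str, b: str) -> dict[str, str]:
        if not self._fitted:
            raise RuntimeError("FeatureExtractor must be fitted before use")
        da, db = self._degree.get(a, 0), self._degree.get(b, 0)
        ra = "gt" if da > db else ("lt" if da < db else "eq")
        pa, pb = self._net.proteins.get(a), self._net.proteins.get(b)
        return {
            "rel_degree": ra,
            "a_kinase": str(int(pa.is_kinase)) if pa else "0",
            "b_kinase": str(int(pb.is_kinase)) if pb else "0",
            "a_ptm": self._ptm_bin(len(pa.ptms) if pa else 0),
            "b_ptm": self._ptm_bin(len(pb.ptms) if pb else 0),
        }


@dataclass
class NaiveBayesModel:
    """Class priors plus per-feature conditional category log-probabilities."""

    alpha: float
    priors: dict[str, float]
    conditionals: dict[str, dict[str, dict[str, float]]]  # feature -> class -> cat -> P
    feature_names: list[str] = field(default_factory=list)

    def validate(self) -> None:
        assert abs(sum(self.priors.values()) - 1.0) < 1e-9
        for feat, per_class in self.conditionals.items():
            for cls, dist in per_class.items():
                total = sum(dist.values())
                assert abs(total - 1.0) < 1e-9, f"{feat}/{cls} sums to {total}"

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "priors": self.priors,
                "conditionals": self.conditionals,
                "feature_names": self.feature_names,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, payload: str) -> "NaiveBayesModel":
        d = json.loads(payload)
        return cls(
            alpha=d["alpha"],
            priors=d["priors"],
            conditionals=d["conditionals"],
            feature_names=d["feature_names"],
        )


def train_naive_bayes(instances, alpha: float = 1.0) -> NaiveBayesModel:
    """Fit category counts with add-``alpha`` smoothing.

    ``instances`` is an iterable of ``(feature_dict, label)`` with labels in
    {forward, reverse}.  Each feature's category vocabulary is the set seen in
    training plus the reserved unknown level, so unseen categories at predict
    time get smoothed (non-zero) probability.
    """
    instances = list(instances)
    if not instances:
        raise ValueError("empty training set")
    labels = sorted({lab for _, lab in instances})
    if len(labels) < 2:
        raise ValueError(f"training set contains a single class {labels}; cannot calibrate")
    feature_names = sorted(instances[0][0])
    for feats, _ in instances:
        if sorted(feats) != feature_names:
            raise ValueError("inconsistent feature schema across instances")

    n_per_class = {lab: 0 for lab in labels}
    counts: dict[str, dict[str, dict[str, int]]] = {
        f: {lab: {} for lab in labels} for f in feature_names
    }
    vocab: dict[str, set] = {f: set() for f in feature_names}
    for feats, lab in instances:
        n_per_class[lab] += 1
        for f in feature_names:
            cat = str(feats[f])
            vocab[f].add(cat)
            counts[f][lab][cat] = counts[f][lab].get(cat, 0) + 1

    n_total = len(instances)
    priors = {lab: n_per_class[lab] / n_total for lab in labels}
    conditionals: dict[str, dict[str, dict[str, float]]] = {}
    for f in feature_names:
        cats = sorted(vocab[f]) + [UNKNOWN]
        k = len(cats)
        conditionals[f] = {}
        for lab in labels:
            denom = n_per_class[lab] + alpha * k
            conditionals[f][lab] = {
                cat: (counts[f][lab].get(cat, 0) + alpha) / denom for cat in cats
            }
    model = NaiveBayesModel(
        alpha=alpha, priors=priors, conditionals=conditionals, feature_names=feature_names
    )
    model.validate()
    return model


def predict_direction(model: NaiveBayesModel, features: dict[str, str]) -> tuple[str, float]:
    """Posterior over {forward, reverse} for one ordered pair.

    Returns ``(argmax class, posterior of that class)``; posteriors of the two
    classes sum to 1.  An exact tie returns ``forward`` (the caller breaks
    edge-level ties toward the lexicographically smaller source).
    """
    if sorted(features) != model.feature_names:
        missing = set(model.feature_names) ^ set(features)
        raise ValueError(f"feature schema mismatch: {sorted(missing)}")
    log_post = {}
    for lab, prior in model.priors.items():
        lp = math.log(prior)
        for f in model.feature_names:
            dist = model.conditionals[f][lab]
            cat = str(features[f])
            lp += math.log(dist.get(cat, dist[UNKNOWN]))
        log_post[lab] = lp
    m = max(log_post.values())
    weights = {lab: math.exp(lp - m) for lab, lp in log_post.items()}
    z = sum(weights.values())
    post = {lab: w / z for lab, w in weights.items()}
    if abs(post[FORWARD] - post[REVERSE]) < 1e-12:
        return FORWARD, 0.5
    lab = max(post, key=post.get)
    return lab, post[lab]


def orient_network(
    net: AnnotatedNetwork,
    model: NaiveBayesModel,
    extractor,
    curated: dict[tuple[str, str], str] | None = None,
    keep_curated: bool = True,
) -> AnnotatedNetwork:
    """Assign exactly one direction (plus posterior) to every edge.

    ``curated`` maps unordered pairs (as sorted tuples) to the known source
    node; with ``keep_curated`` (default) those edges keep their curated
    direction regardless of the classifier's vote.
    """
    curated = curated or {}
    oriented = AnnotatedNetwork(isoform_ids=net.isoform_ids)
    for pid, rec in net.proteins.items():
        oriented.add_protein(rec)
    for e in net.edges:
        pair = tuple(sorted((e.a, e.b)))
        if keep_curated and pair in curated:
            oriented.add_edge(e.oriented(curated[pair], 1.0))
            continue
        feats = extractor(e.a, e.b)
        lab, post = predict_direction(model, feats)
        if abs(post - 0.5) < 1e-12:
            source = min(e.a, e.b)  # deterministic tie-break
        else:
            source = e.a if lab == FORWARD else e.b
        oriented.add_edge(e.oriented(source, post))
    return oriented
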