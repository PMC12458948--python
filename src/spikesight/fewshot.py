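"""K-shot prototype classification over frozen embeddings.

For each class, K support embeddings are averaged and renormalized into a
unit-norm prototype.  A query is scored by cosine similarity to every
prototype (a dot product, since everything is unit-norm), the similarities
pass through a temperature-scaled softmax, and the query is assigned the
argmax class — or ``Unknown`` when the top probability falls below the
rejection threshold.  The episode harness samples K supports per class
without replacement, classifies all remaining labeled records as queries,
and reports accuracies and a confusion matrix per (K, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax as _softmax
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from spikesight.embedding import EmbeddingVector, EncoderHandle, embed_image, embed_timeseries
from spikesight.imaging import RenderConfig, render_panel

UNKNOWN_LABEL = "Unknown"


@dataclass(frozen=True)
class SupportSet:
    """Per-class lists of support embeddings (>= 1 per class, one shared dim)."""

    embeddings: dict  # label -> list[EmbeddingVector]

    def __post_init__(self) -> None:
        if not self.embeddings:
            raise ValueError("empty support set")
        dims = set()
        for label, vecs in self.embeddings.items():
            if not vecs:
                raise ValueError(f"class {label!r} has no support embeddings")
            dims.update(v.values.size for v in vecs)
        if len(dims) != 1:
            raise ValueError("support embeddings have mixed dimensions")

    @property
    def labels(self) -> tuple:
        return tuple(sorted(self.embeddings))


@dataclass(frozen=True)
class ClassPrototypes:
    """Unit-norm per-class prototype embeddings."""

    prototypes: dict  # label -> EmbeddingVector

    @property
    def labels(self) -> tuple:
        return tuple(sorted(self.prototypes))

    def matrix(self) -> np.ndarray:
        return np.stack([self.prototypes[c].values for c in self.labels])


@dataclass(frozen=True)
class ClassificationResult:
    predicted_label: str
    similarities: dict
    probabilities: dict
    unknown_flag: bool = False
    tie_flag: bool = False


@dataclass(frozen=True)
class EpisodeSpec:
    """Provenance of one few-shot episode."""

    k: int
    classes: tuple
    seed: int
    temperature: float
    unknown_threshold: float
    query_unit_ids: tuple = ()


@dataclass
class EvalReport:
    """Accuracy summary of a K-shot evaluation protocol."""

    class_labels: tuple
    overall_accuracy: dict = field(default_factory=dict)   # (K, seed) -> float
    per_class_accuracy: dict = field(default_factory=dict)  # (K, seed) -> {label: float}
    confusion: dict = field(default_factory=dict)           # (K, seed) -> ndarray
    episodes: list = field(default_factory=list)

    def mean_accuracy(self, k: int) -> float:
        vals = [a for (kk, _), a in self.overall_accuracy.items() if kk == k]
        return float(np.mean(vals))

    def accuracy_values(self, k: int) -> np.ndarray:
        return np.array(
            [a for (kk, _), a in sorted(self.overall_accuracy.items()) if kk == k]
        )


def build_prototypes(support: SupportSet) -> ClassPrototypes:
    """Mean-then-renormalize class prototypes from a support set."""
    prototypes = {}
    for label in support.labels:
        stack = np.stack([v.values for v in support.embeddings[label]])
        mean = stack.mean(axis=0)
        norm = np.linalg.norm(mean)
        if norm < 1e-12:
            raise ValueError(f"degenerate prototype for class {label!r}: zero-norm mean")
        prototypes[label] = EmbeddingVector(mean / norm)
    return ClassPrototypes(prototypes)


def classify_query(
    query: EmbeddingVector,
    prototypes: ClassPrototypes,
    temperature: float = 1.0,
    unknown_threshold: float = 0.5,
) -> ClassificationResult:
    """Nearest-prototype-by-cosine classification with softmax scoring.

    Probabilities are ``softmax(similarities / temperature)``.  The query is
    marked ``Unknown`` when the top probability is below
    ``unknown_threshold``.  Exact probability ties are broken
    lexicographically by label with ``tie_flag`` set.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if not 0 <= unknown_threshold < 1:
        raise ValueError("unknown_threshold must be in [0, 1)")
    labels = prototypes.labels
    proto_mat = prototypes.matrix()
    if query.values.size != proto_mat.shape[1]:
        raise ValueError("embedding dim mismatch between query and prototypes")
    sims = proto_mat @ query.values
    probs = _softmax(sims / temperature)
    best = int(np.argmax(probs))  # argmax -> lowest index on ties; labels sorted
    tie = bool(np.sum(np.isclose(probs, probs[best], rtol=0, atol=1e-12)) > 1)
    unknown = bool(probs[best] < unknown_threshold)
    return ClassificationResult(
        predicted_label=UNKNOWN_LABEL if unknown else labels[best],
        similarities=dict(zip(labels, sims.tolist())),
        probabilities=dict(zip(labels, probs.tolist())),
        unknown_flag=unknown,
        tie_flag=tie,
    )


def embed_records(
    records,
    encoder: EncoderHandle,
    render_config: RenderConfig | None = None,
    representation: str = "image",
):
    """Embed NeuronRecords either via rendered composite panels or raw series."""
    if representation == "image":
        cfg = render_config or RenderConfig()
        return [embed_image(encoder, render_panel(r, cfg)) for r in records]
    if representation == "timeseries":
        cfg = render_config or RenderConfig()
        return [embed_timeseries(r, cfg.composite_layout) for r in records]
    raise ValueError(f"unknown representation {representation!r}")


def run_kshot_evaluation(
    records,
    encoder: EncoderHandle,
    k_values=(1, 2, 4, 8),
    n_seeds: int = 5,
    temperature: float = 1.0,
    unknown_threshold: float = 0.0,
    render_config: RenderConfig | None = None,
    representation: str = "image",
    base_seed: int = 0,
    precomputed_embeddings=None,
) -> EvalReport:
    """Episode-based K-shot evaluation on labeled records.

    Per (K, seed): K support records per class are sampled without
    replacement, every remaining labeled record is classified as a query,
    and overall / per-class accuracy plus a confusion matrix are recorded.
    Fully reproducible given ``base_seed``.  ``unknown_threshold`` defaults
    to 0 here so accuracy measures pure prototype assignment.
    """
    labeled = [r for r in records if r.label is not None]
    by_class: dict = {}
    for i, r in enumerate(labeled):
        by_class.setdefault(r.label, []).append(i)
    if len(by_class) < 2:
        raise ValueError("need >= 2 labeled classes")
    max_k = max(k_values)
    for label, idx in by_class.items():
        if len(idx) <= max_k:
            raise ValueError(f"insufficient support: class {label!r} has {len(idx)} records")

    if precomputed_embeddings is None:
        embeddings = embed_records(labeled, encoder, render_config, representation)
    else:
        embeddings = list(precomputed_embeddings)
    class_labels = tuple(sorted(by_class))
    label_pos = {c: j for j, c in enumerate(class_labels)}
    report = EvalReport(class_labels=class_labels)

    for k in k_values:
        for s in range(n_seeds):
            seed = base_seed * 10_000 + k * 100 + s
            rng = np.random.default_rng(seed)
            support_idx, query_idx = [], []
            for label in class_labels:
                idx = np.array(by_class[label])
                chosen = rng.choice(idx, size=k, replace=False)
                support_idx.extend(chosen.tolist())
                query_idx.extend(np.setdiff1d(idx, chosen).tolist())
            support = SupportSet(
                {
                    label: [embeddings[i] for i in by_class[label] if i in set(support_idx)]
                    for label in class_labels
                }
            )
            prototypes = build_prototypes(support)
            confusion = np.zeros((len(class_labels), len(class_labels)), dtype=np.int64)
            for qi in query_idx:
                res = classify_query(embeddings[qi], prototypes, temperature, unknown_threshold)
                true = label_pos[labeled[qi].label]
                if res.predicted_label in label_pos:
                    confusion[true, label_pos[res.predicted_label]] += 1
            n_queries_per_class = confusion.sum(axis=1)
            correct = np.diag(confusion)
            report.overall_accuracy[(k, s)] = float(correct.sum() / max(1, len(query_idx)))
            report.per_class_accuracy[(k, s)] = {
                c: float(correct[j] / n_queries_per_class[j]) if n_queries_per_class[j] else 0.0
                for j, c in enumerate(class_labels)
            }
            report.confusion[(k, s)] = confusion
            report.episodes.append(
                EpisodeSpec(
                    k=k,
                    classes=class_labels,
                    seed=seed,
                    temperature=temperature,
                    unknown_threshold=unknown_threshold,
                    query_unit_ids=tuple(labeled[i].unit_id for i in query_idx),
                )
            )
    return report


def fit_embedding_classifier(
    embeddings, labels, test_fraction: float = 0.05, seed: int = 0
):
    """Random-forest benchmark on embeddings with a stratified held-out split.

    Returns ``(accuracy, confusion_matrix, class_labels)`` on the held-out
    fraction (default 5%).
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    X = np.stack([e.values if isinstance(e, EmbeddingVector) else np.asarray(e) for e in embeddings])
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need >= 2 classes")
    try:
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=test_fraction, random_state=seed, stratify=y
        )
    except ValueError as exc:
        raise ValueError(f"split too small: {exc}") from exc
    if set(np.unique(y_tr)) != set(classes):
        raise ValueError("split too small: a class is absent from the train split")
    clf = RandomForestClassifier(n_estimators=200, random_state=seed)
    clf.fit(X_tr, y_tr)
    pred = clf.predict(X_te)
    accuracy = float(np.mean(pred == y_te))
    confusion = np.zeros((classes.size, classes.size), dtype=np.int64)
    pos = {c: j for j, c in enumerate(classes)}
    for t, p in zip(y_te, pred):
        confusion[pos[t], pos[p]] += 1
    return accuracy, confusion, tuple(classes)
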