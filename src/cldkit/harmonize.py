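"""Merge free-text variable proposals from multiple experts.

Asynchronous expert elicitation yields many near-duplicate variable
labels ("Physical activity", "Exercise/physical activity") and families
of conceptually related ones ("Cortisol", "HPA axis activity").  This
module harmonizes them:

1. normalize labels (lowercase, strip punctuation, remove stopwords);
2. embed each label (mean of word vectors, or a sentence vector);
3. flag candidate duplicate pairs above a cosine-similarity threshold
   (default 0.8) for reviewer attention;
4. cluster labels by average-linkage agglomeration on cosine distance,
   cut at a similarity threshold (default 0.58, selectable from a
   cutoff/pair-count curve with the kneedle knee-point rule);
5. score each cluster by the sum of its members' importance ratings
   (1-3) and include it as a key variable when the sum reaches a
   cutoff (default 3 — one high-importance vote or three low ones).

The final naming and synthesis of merged variables remains a human
decision; the pipeline outputs candidate clusters with representative
labels and scores.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .embeddings import EmbeddingProvider

#: Minimal built-in stopword list: articles, copulas, a few prepositions
#: and conjunctions.  Deliberately small and recorded in every merge
#: manifest so runs are reproducible without an external wordlist.
DEFAULT_STOPWORDS: frozenset[str] = frozenset(
    {
        "a", "an", "the",
        "is", "are", "was", "were", "be", "been", "being",
        "of", "in", "on", "at", "to", "for", "with", "by", "from",
        "and", "or",
    }
)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class VariableProposal:
    """One expert's free-text variable proposal with an importance rating."""

    expert_id: str
    raw_label: str
    motivation: str = ""
    rating: int = 1

    def __post_init__(self) -> None:
        if self.rating not in (1, 2, 3):
            raise ValueError(
                f"rating must be in {{1,2,3}} (3 = high importance), got {self.rating}"
            )
        if not self.raw_label.strip():
            raise ValueError("raw_label must be non-empty")


@dataclass(frozen=True)
class MergeConfig:
    """Thresholds and token handling for harmonization.

    ``pair_flag_threshold`` flags candidate duplicates (strictly
    greater-than); ``cluster_threshold`` is the similarity at which
    agglomeration stops (implemented as distance 1 - s on the
    average-linkage dendrogram).  Linkage is fixed to average, which
    damps outlier influence and yields a monotone dendrogram.
    """

    stopwords: frozenset[str] = DEFAULT_STOPWORDS
    pair_flag_threshold: float = 0.8
    cluster_threshold: float = 0.58
    linkage: str = "average"

    def __post_init__(self) -> None:
        for name in ("pair_flag_threshold", "cluster_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.linkage != "average":
            raise ValueError("linkage is fixed to 'average'")


@dataclass(frozen=True)
class ClusterResult:
    """A partition of proposal indices with per-cluster scores.

    ``clusters[k]`` lists member indices; ``representative_labels[k]``
    is the member label with the highest summed within-cluster
    similarity (a suggestion — final naming is an expert decision);
    ``summed_ratings[k]`` sums member importance ratings; ``included[k]``
    applies the rating cutoff.
    """

    clusters: tuple[tuple[int, ...], ...]
    representative_labels: tuple[str, ...]
    summed_ratings: tuple[int, ...]
    included: tuple[bool, ...]

    def as_frame(self, labels: Sequence[str] | None = None) -> pd.DataFrame:
        rows = []
        for k, members in enumerate(self.clusters):
            rows.append(
                {
                    "cluster": k,
                    "members": ";".join(
                        labels[i] if labels is not None else str(i) for i in members
                    ),
                    "representative": self.representative_labels[k],
                    "summed_rating": self.summed_ratings[k],
                    "included": self.included[k],
                }
            )
        return pd.DataFrame(rows)


def normalize_label(text: str, stopwords: frozenset[str] = DEFAULT_STOPWORDS) -> list[str]:
    """Lowercased, punctuation-stripped tokens with stopwords removed.

    Order is preserved; the result may be empty (e.g. a stopword-only
    label).
    """
    return [t for t in _TOKEN_RE.findall(text.lower()) if t not in stopwords]


class UnembeddableLabel(ValueError):
    """No token of the label is in the provider's vocabulary."""


def phrase_embedding(
    text: str,
    provider: EmbeddingProvider,
    config: MergeConfig | None = None,
) -> np.ndarray | None:
    """Mean of word vectors over normalized in-vocabulary tokens.

    Out-of-vocabulary tokens are skipped; returns ``None`` when no token
    can be embedded, so callers can route the proposal to manual review
    rather than silently dropping it.
    """
    config = config or MergeConfig()
    tokens = normalize_label(text, config.stopwords)
    vectors = [provider.word_vector(t) for t in tokens]
    vectors = [v for v in vectors if v is not None]
    if not vectors:
        return None
    return np.mean(vectors, axis=0)


def pairwise_similarity(vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Symmetric cosine-similarity matrix with unit diagonal."""
    matrix = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(matrix, axis=1)
    if np.any(norms == 0):
        bad = int(np.argmax(norms == 0))
        raise ValueError(f"vector {bad} has zero norm; cosine similarity undefined")
    unit = matrix / norms[:, None]
    sim = unit @ unit.T
    np.fill_diagonal(sim, 1.0)
    return np.clip(sim, -1.0, 1.0)


def flag_similar_pairs(
    matrix: np.ndarray, threshold: float = 0.8
) -> list[tuple[int, int]]:
    """Unordered index pairs with similarity strictly above the threshold.

    Sorted by descending similarity (then by index) so reviewers see the
    most likely duplicates first.
    """
    n = matrix.shape[0]
    pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if matrix[i, j] > threshold
    ]
    return sorted(pairs, key=lambda p: (-matrix[p[0], p[1]], p[0], p[1]))


def cluster_variables(
    matrix: np.ndarray, config: MergeConfig | None = None
) -> tuple[tuple[int, ...], ...]:
    """Average-linkage agglomeration on cosine distance 1 - similarity.

    Clusters are merged while linkage distance stays at or below
    ``1 - cluster_threshold``; equal-distance merges follow scipy's
    deterministic lowest-index order.  Returns the partition as tuples
    of member indices, clusters ordered by smallest member.
    """
    config = config or MergeConfig()
    n = matrix.shape[0]
    if n == 0:
        return ()
    if n == 1:
        return ((0,),)
    distance = 1.0 - matrix
    np.fill_diagonal(distance, 0.0)
    condensed = squareform(np.maximum(distance, 0.0), checks=False)
    tree = linkage(condensed, method=config.linkage)
    flat = fcluster(tree, t=1.0 - config.cluster_threshold, criterion="distance")
    groups: dict[int, list[int]] = {}
    for idx, cid in enumerate(flat):
        groups.setdefault(int(cid), []).append(idx)
    return tuple(
        tuple(members) for members in sorted(groups.values(), key=lambda m: m[0])
    )


def kneedle_threshold(
    curve: Sequence[tuple[float, float]], sensitivity: float = 0.01
) -> float | None:
    """Knee of a cutoff -> flagged-pair-count curve (kneedle rule).

    Both axes are normalized to [0, 1]; the knee is the cutoff
    maximizing the deviation of the normalized curve from the chord
    joining its endpoints.  Returns ``None`` when the maximum deviation
    does not exceed ``sensitivity`` (e.g. a perfectly linear curve).

    The cutoffs must be strictly monotone and the counts monotone
    non-increasing in the cutoff (lowering the cutoff can only flag more
    pairs).
    """
    if len(curve) < 3:
        raise ValueError("kneedle needs at least 3 points")
    pts = sorted(curve)
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.any(np.diff(x) <= 0):
        raise ValueError("cutoffs must be strictly monotone")
    if np.any(np.diff(y) > 0):
        raise ValueError("pair counts must be non-increasing in the cutoff")
    x_n = (x - x[0]) / (x[-1] - x[0])
    if y[-1] == y[0]:
        return None
    y_n = (y - y.min()) / (y.max() - y.min())
    chord = y_n[0] + (y_n[-1] - y_n[0]) * x_n
    deviation = np.abs(y_n - chord)
    best = int(np.argmax(deviation))
    if deviation[best] <= sensitivity:
        return None
    return float(x[best])


def aggregate_ratings(
    clusters: Sequence[Sequence[int]],
    proposals: Sequence[VariableProposal],
    cutoff: int = 3,
    similarity: np.ndarray | None = None,
) -> ClusterResult:
    """Sum member importance ratings per cluster and apply the inclusion rule.

    A cluster is included as a key variable when its summed rating
    reaches ``cutoff`` — so one expert rating a variable "high
    importance" (3) suffices, as do three independent low-importance
    proposals.  When a similarity matrix over the proposals is supplied,
    the representative label is the member with the highest summed
    within-cluster similarity; otherwise the lowest-index member.
    """
    assigned = sorted(i for members in clusters for i in members)
    if assigned != list(range(len(proposals))):
        raise ValueError("clusters must partition the proposals exactly")

    reps: list[str] = []
    sums: list[int] = []
    included: list[bool] = []
    for members in clusters:
        members = tuple(members)
        sums.append(sum(proposals[i].rating for i in members))
        included.append(sums[-1] >= cutoff)
        if similarity is not None and len(members) > 1:
            scores = {
                i: sum(similarity[i, j] for j in members if j != i) for i in members
            }
            rep = min(members, key=lambda i: (-scores[i], i))
        else:
            rep = members[0]
        reps.append(proposals[rep].raw_label)
    return ClusterResult(
        clusters=tuple(tuple(m) for m in clusters),
        representative_labels=tuple(reps),
        summed_ratings=tuple(sums),
        included=tuple(included),
    )


@dataclass(frozen=True)
class MergeReport:
    """Full output of one harmonization run.

    ``unembeddable`` lists proposal indices routed to manual review
    (kept as singleton clusters in the result, never dropped);
    ``manifest`` records the configuration for reproducibility.
    """

    result: ClusterResult
    flagged_pairs: tuple[tuple[int, int], ...]
    unembeddable: tuple[int, ...]
    manifest: dict = field(default_factory=dict)


def merge_proposals(
    proposals: Sequence[VariableProposal],
    provider: EmbeddingProvider,
    config: MergeConfig | None = None,
    rating_cutoff: int = 3,
) -> MergeReport:
    """Run the full harmonization pipeline over a proposal list."""
    config = config or MergeConfig()
    embeddings: list[np.ndarray | None] = [
        phrase_embedding(p.raw_label, provider, config) for p in proposals
    ]
    embeddable = [i for i, v in enumerate(embeddings) if v is not None]
    unembeddable = tuple(i for i, v in enumerate(embeddings) if v is None)

    if embeddable:
        sim_local = pairwise_similarity([embeddings[i] for i in embeddable])
        flagged_local = flag_similar_pairs(sim_local, config.pair_flag_threshold)
        clusters_local = cluster_variables(sim_local, config)
    else:
        sim_local = np.zeros((0, 0))
        flagged_local = []
        clusters_local = ()

    # map back to original indices; unembeddable proposals stay singletons
    to_orig = {k: i for k, i in enumerate(embeddable)}
    clusters = [tuple(to_orig[k] for k in members) for members in clusters_local]
    clusters.extend((i,) for i in unembeddable)
    clusters.sort(key=lambda m: m[0])

    full_sim = None
    if embeddable:
        full_sim = np.eye(len(proposals))
        for a, i in enumerate(embeddable):
            for b, j in enumerate(embeddable):
                full_sim[i, j] = sim_local[a, b]

    result = aggregate_ratings(clusters, proposals, rating_cutoff, full_sim)
    manifest = {
        "provider": getattr(provider, "name", type(provider).__name__),
        "pair_flag_threshold": config.pair_flag_threshold,
        "cluster_threshold": config.cluster_threshold,
        "linkage": config.linkage,
        "rating_cutoff": rating_cutoff,
        "stopwords": sorted(config.stopwords),
        "n_proposals": len(proposals),
        "n_unembeddable": len(unembeddable),
    }
    return MergeReport(
        result=result,
        flagged_pairs=tuple(
            (to_orig[a], to_orig[b]) for a, b in flagged_local
        ),
        unembeddable=unembeddable,
        manifest=manifest,
    )
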