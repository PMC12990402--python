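"""Synthetic diagrams, elicitation datasets, and the brute-force loop oracle.

Everything the analysis pipeline consumes can be generated here so that
each stage is testable offline:

* :func:`random_cld` draws a seeded random diagram matching requested
  counts *exactly* (variables per domain, connections, polarity quotas,
  exogenous set size) — the default shape mirrors the published young
  adult sleep diagram: 29 variables (5 biological / 7 psychological /
  9 behavioral / 8 social), 175 connections of which 58 negative and
  2 ambiguous, and 3 exogenous variables;
* :func:`published_fixtures` returns the two small sub-diagrams printed in
  the source figures (the sleep / depressive-symptoms / smoking triad,
  and the six-variable cross-scale well-being loop);
* :func:`synth_elicitation` plants synonym clusters with a matching
  fixture embedding provider and returns the ground-truth partition;
* :func:`brute_force_loop_oracle` enumerates cycles by exhaustively
  testing vertex sequences — the independent oracle the fast
  enumerator is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations, permutations

import numpy as np
import pandas as pd

from .core import DOMAINS, CausalLoopDiagram, Connection, Variable
from .embeddings import FixtureEmbeddingProvider
from .harmonize import VariableProposal
from .loops import Loop, canonical_rotation


@dataclass(frozen=True)
class SynthCldSpec:
    """Exact composition of a random diagram.

    Defaults reproduce the published diagram's summary shape.
    """

    n_variables: int = 29
    n_connections: int = 175
    negative_count: int = 58
    ambiguous_count: int = 2
    n_exogenous: int = 3
    domain_counts: tuple[int, int, int, int] = (5, 7, 9, 8)  # bio/psych/behav/social
    seed: int = 0


class UnsatisfiableSpec(ValueError):
    """The requested composition cannot be realized; names the constraint."""


def random_cld(spec: SynthCldSpec) -> CausalLoopDiagram:
    """Seeded random diagram meeting every requested count exactly.

    Edges are placed uniformly over the allowed ordered pairs (targets
    must be endogenous, no self-loops, no duplicates), with one
    incoming edge guaranteed per endogenous variable first so the
    exogenous set is exactly the requested one.  Polarities are
    assigned by exact quota shuffling, not independent coin flips.
    The same seed yields an identical diagram.
    """
    n, m = spec.n_variables, spec.n_connections
    if sum(spec.domain_counts) != n:
        raise UnsatisfiableSpec(
            f"domain_counts sum to {sum(spec.domain_counts)}, need n_variables={n}"
        )
    if spec.n_exogenous >= n and m > 0:
        raise UnsatisfiableSpec("every variable exogenous leaves no edge targets")
    n_endo = n - spec.n_exogenous
    if m < n_endo:
        raise UnsatisfiableSpec(
            f"n_connections={m} cannot give every endogenous variable an incoming "
            f"edge (need >= {n_endo})"
        )
    if m > (n - 1) * n_endo:
        raise UnsatisfiableSpec(
            f"n_connections={m} exceeds the {(n - 1) * n_endo} ordered pairs with "
            "an endogenous target"
        )
    if spec.negative_count + spec.ambiguous_count > m:
        raise UnsatisfiableSpec("polarity quotas exceed n_connections")

    rng = np.random.default_rng(spec.seed)
    width = len(str(n - 1))
    ids, variables = [], []
    k = 0
    for domain, count in zip(DOMAINS, spec.domain_counts):
        for _ in range(count):
            vid = f"v{k:0{width}d}-{domain[:4]}"
            ids.append(vid)
            variables.append(Variable(vid, vid, domain))
            k += 1

    exo = set(rng.choice(ids, size=spec.n_exogenous, replace=False).tolist())
    endo = [i for i in ids if i not in exo]

    # guarantee in-degree >= 1 for every endogenous variable
    edges: set[tuple[str, str]] = set()
    for tgt in endo:
        sources = [s for s in ids if s != tgt]
        src = sources[int(rng.integers(len(sources)))]
        edges.add((src, tgt))
    # fill remaining quota uniformly over the still-free allowed pairs
    free = [
        (s, t) for s in ids for t in endo if s != t and (s, t) not in edges
    ]
    extra = m - len(edges)
    idx = rng.choice(len(free), size=extra, replace=False)
    edges.update(free[int(i)] for i in idx)

    polarities = (
        ["negative"] * spec.negative_count
        + ["ambiguous"] * spec.ambiguous_count
        + ["positive"] * (m - spec.negative_count - spec.ambiguous_count)
    )
    rng.shuffle(polarities)
    connections = [
        Connection(s, t, p) for (s, t), p in zip(sorted(edges), polarities)
    ]
    return CausalLoopDiagram(
        variables,
        connections,
        name=f"synthetic-cld-seed{spec.seed}",
        provenance=f"random_cld({spec})",
    )


def published_fixtures() -> dict[str, CausalLoopDiagram]:
    """The two printed sub-diagrams, loaded from packaged native files.

    ``triad``: sleep disturbance, affective symptoms of depression and
    smoking with all six directed positive connections (five loops, all
    reinforcing).  ``wb_loop``: the six-variable cross-scale loop through
    well-being with four negative and two positive connections.
    """
    from .io import cld_from_dict
    import json

    out = {}
    for name in ("smoking_triad", "well_being_loop"):
        text = resources.files("cldkit.fixtures").joinpath(f"{name}.json").read_text()
        out[name] = cld_from_dict(json.loads(text))
    return out


# ---- synthetic elicitation -----------------------------------------


@dataclass(frozen=True)
class SynthElicitationSpec:
    """Planted-synonym elicitation design.

    Each concept gets a distinct anchor direction; its synonyms get the
    anchor plus a small perturbation, so within-group cosine similarity
    exceeds between-group similarity by construction.  ``noise`` in
    [0, 1] scales extra per-synonym perturbation that erodes the gap.
    """

    n_concepts: int = 3
    synonyms_per_concept: int = 4
    rating_probs: tuple[float, float, float] = (0.25, 0.5, 0.25)  # P(rating = 1,2,3)
    noise: float = 0.0
    dimension: int = 32
    seed: int = 0


@dataclass(frozen=True)
class ElicitationDataset:
    proposals: tuple[VariableProposal, ...]
    provider: FixtureEmbeddingProvider
    planted_partition: tuple[tuple[int, ...], ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "expert_id": p.expert_id,
                    "raw_label": p.raw_label,
                    "motivation": p.motivation,
                    "rating": p.rating,
                }
                for p in self.proposals
            ]
        )


def synth_elicitation(spec: SynthElicitationSpec) -> ElicitationDataset:
    """Generate proposals with planted synonym groups and their provider.

    Labels are single pseudo-words (one token per proposal) so the word
    and sentence embedding stages coincide; the fixture provider's table
    holds exactly these tokens.  Deterministic in the seed.
    """
    if spec.n_concepts < 1 or spec.synonyms_per_concept < 1:
        raise ValueError("need at least one concept and one synonym each")
    if not 0.0 <= spec.noise <= 1.0:
        raise ValueError("noise must be in [0, 1]")
    rng = np.random.default_rng(spec.seed)

    # near-orthogonal anchors: QR of a seeded Gaussian matrix
    if spec.n_concepts > spec.dimension:
        raise ValueError("dimension must be >= n_concepts for distinct anchors")
    gauss = rng.standard_normal((spec.dimension, spec.n_concepts))
    anchors, _ = np.linalg.qr(gauss)
    anchors = anchors.T  # one orthonormal anchor per concept

    base_sigma, noise_sigma = 0.05, 0.8
    proposals: list[VariableProposal] = []
    table: dict[str, np.ndarray] = {}
    partition: list[tuple[int, ...]] = []
    idx = 0
    for c in range(spec.n_concepts):
        members = []
        for s in range(spec.synonyms_per_concept):
            token = f"concept{c:02d}syn{s:02d}"
            vec = anchors[c] + base_sigma * rng.standard_normal(spec.dimension)
            if spec.noise > 0:
                vec = vec + spec.noise * noise_sigma * rng.standard_normal(spec.dimension)
            table[token] = vec / np.linalg.norm(vec)
            rating = int(rng.choice([1, 2, 3], p=spec.rating_probs))
            proposals.append(
                VariableProposal(
                    expert_id=f"expert{int(rng.integers(1, 15)):02d}",
                    raw_label=token,
                    motivation=f"synthetic motivation for {token}",
                    rating=rating,
                )
            )
            members.append(idx)
            idx += 1
        partition.append(tuple(members))

    provider = FixtureEmbeddingProvider(table, name=f"planted-seed{spec.seed}")
    return ElicitationDataset(
        proposals=tuple(proposals),
        provider=provider,
        planted_partition=tuple(partition),
    )


def random_small_spec(seed: int, max_variables: int = 8) -> SynthCldSpec:
    """Seeded spec for a small random diagram (oracle-equivalence studies).

    Samples 3..max_variables variables, a random domain split, 0-1
    exogenous variables and a feasible edge count with random polarity
    quotas.  Small enough for :func:`brute_force_loop_oracle`.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_variables + 1))
    cuts = sorted(rng.integers(0, n + 1, size=3).tolist())
    domain_counts = (cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1], n - cuts[2])
    n_exogenous = int(rng.integers(0, 2))
    n_endo = n - n_exogenous
    m = int(rng.integers(n_endo, (n - 1) * n_endo + 1))
    negative = int(rng.integers(0, m + 1))
    ambiguous = int(rng.integers(0, m - negative + 1)) if m > negative else 0
    return SynthCldSpec(
        n_variables=n,
        n_connections=m,
        negative_count=negative,
        ambiguous_count=ambiguous,
        n_exogenous=n_exogenous,
        domain_counts=domain_counts,
        seed=int(rng.integers(0, 2**31)),
    )


# ---- brute-force oracle --------------------------------------------


def brute_force_loop_oracle(
    cld: CausalLoopDiagram, max_length: int, min_length: int = 2
) -> list[Loop]:
    """Enumerate cycles by testing every vertex sequence up to a length.

    For each vertex subset of size k the candidate cyclic orders are all
    permutations anchored at the subset's smallest id (one per rotation
    class), accepted when every consecutive connection exists.  This is
    exhaustive and entirely independent of the depth-first enumerator,
    and factorially slow — guarded to diagrams of at most 10 variables.
    """
    ids = cld.variable_ids
    if len(ids) > 10:
        raise ValueError("brute-force oracle is limited to 10 variables")
    has = cld.has_connection
    loops: list[Loop] = []
    for k in range(max(2, min_length), min(max_length, len(ids)) + 1):
        for subset in combinations(ids, k):
            head, rest = subset[0], subset[1:]
            for perm in permutations(rest):
                seq = (head, *perm)
                if all(has(seq[i], seq[(i + 1) % k]) for i in range(k)):
                    loops.append(Loop.from_sequence(cld, seq))
    return sorted(loops, key=lambda l: (l.length, l.sequence))
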