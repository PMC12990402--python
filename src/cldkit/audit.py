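"""Mediation audit for proposed direct causal connections.

A causal connection may be empirically supported yet still indirect: its
underlying mechanism can already be represented by other diagram
variables, in which case drawing a direct edge double-counts the
pathway.  Given the candidate intermediary mechanisms named for an edge,
the audit applies a three-way decision rule:

1. retain the direct connection if at least one mechanism is *not* a
   diagram variable (something outside the model mediates it);
2. replace it with an indirect path through the matched variables if
   mechanisms were named and all of them are already diagram variables;
3. remove it if no plausible mechanism was identified at all.

Mechanism-to-variable matching reuses the harmonization similarity
machinery (same embedding provider, same pair threshold) so the package
has a single notion of "is already a CLD variable"; an exact label or id
match short-circuits the embedding comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import slugify
from .core import CausalLoopDiagram
from .embeddings import EmbeddingProvider
from .harmonize import MergeConfig, normalize_label, phrase_embedding

ACTIONS = ("retain", "replace_with_path", "remove")


@dataclass(frozen=True)
class MechanismMatch:
    """One mechanism resolved (or not) against the diagram's variables."""

    mechanism: str
    variable_id: str | None
    similarity: float

    @property
    def matched(self) -> bool:
        return self.variable_id is not None


@dataclass(frozen=True)
class MechanismAssessment:
    """Outcome of auditing one direct connection.

    ``suggested_path`` is populated only for ``replace_with_path`` and
    routes source -> matched mechanism variable(s) -> target, matched
    variables ordered by descending similarity (a reporting convention;
    polarities along the rerouted path are left to expert judgment).
    """

    edge: tuple[str, str]
    mechanisms: tuple[str, ...]
    matches: tuple[MechanismMatch, ...]
    action: str
    suggested_path: tuple[str, ...] = ()


def match_mechanism(
    cld: CausalLoopDiagram,
    mechanism: str,
    provider: EmbeddingProvider,
    config: MergeConfig | None = None,
) -> MechanismMatch:
    """Resolve one mechanism label against the diagram's variables.

    Exact id/label match (case- and punctuation-insensitive) wins with
    similarity 1.0; otherwise the best cosine similarity between the
    mechanism's phrase embedding and each variable's label embedding is
    taken, and must strictly exceed ``config.pair_flag_threshold``.
    An unembeddable mechanism is unmatched (conservative: the edge is
    then retained for manual review).
    """
    config = config or MergeConfig()
    slug = slugify(mechanism) if normalize_label(mechanism, frozenset()) else None
    if slug:
        for v in cld.variables:
            if v.id == slug or slugify(v.label) == slug:
                return MechanismMatch(mechanism, v.id, 1.0)

    mech_vec = phrase_embedding(mechanism, provider, config)
    if mech_vec is None:
        return MechanismMatch(mechanism, None, 0.0)
    mech_vec = mech_vec / np.linalg.norm(mech_vec)

    best_id, best_sim = None, -1.0
    for v in cld.variables:
        var_vec = phrase_embedding(v.label, provider, config)
        if var_vec is None:
            continue
        sim = float(mech_vec @ (var_vec / np.linalg.norm(var_vec)))
        if sim > best_sim or (sim == best_sim and best_id is not None and v.id < best_id):
            best_id, best_sim = v.id, sim
    if best_id is not None and best_sim > config.pair_flag_threshold:
        return MechanismMatch(mechanism, best_id, best_sim)
    return MechanismMatch(mechanism, None, max(best_sim, 0.0))


def audit_direct_connection(
    cld: CausalLoopDiagram,
    edge: tuple[str, str],
    mechanisms: list[str] | tuple[str, ...],
    provider: EmbeddingProvider,
    config: MergeConfig | None = None,
) -> MechanismAssessment:
    """Apply the retain / replace-with-path / remove rule to one edge."""
    source, target = edge
    for endpoint in (source, target):
        if not cld.has_variable(endpoint):
            raise KeyError(f"edge endpoint {endpoint!r} is not a diagram variable")
    config = config or MergeConfig()

    matches = tuple(
        match_mechanism(cld, m, provider, config) for m in mechanisms
    )
    if not matches:
        action, path = "remove", ()
    elif all(m.matched for m in matches):
        action = "replace_with_path"
        # de-duplicate matched variables, order by descending similarity
        seen: dict[str, float] = {}
        for m in matches:
            assert m.variable_id is not None
            seen[m.variable_id] = max(seen.get(m.variable_id, -1.0), m.similarity)
        ordered = sorted(seen, key=lambda vid: (-seen[vid], vid))
        path = (source, *ordered, target)
    else:
        action, path = "retain", ()
    return MechanismAssessment(
        edge=(source, target),
        mechanisms=tuple(mechanisms),
        matches=matches,
        action=action,
        suggested_path=path,
    )
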