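"""Probeset -> UniGene -> gene symbol -> EC mapping and probe-score collapse.

Microarray probesets are collapsed to Enzyme Commission (EC) activity level
rather than to gene level, so that isozymes — distinct genes catalysing the
same reaction — pool into a single entry per catalytic activity.  This avoids
over-weighting activities that happen to be encoded by many genes and makes
the downstream set statistic a statement about flux capacity through a
reaction rather than about gene identity.

Two collapse rules are supported:

``average``
    arithmetic mean of the contributing probeset scores (used for the
    ranked list fed to enrichment), and
``max_abs``
    the signed score of the contributing probeset with the largest absolute
    value (used for per-enzyme heat-map tables).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EnzymeMap",
    "CollapsedScores",
    "resolve_enzymes",
    "collapse_scores",
    "uncovered_ecs",
]

#: unmapped-report reason strings, by the layer that failed
REASON_NO_UNIGENE = "no UniGene"
REASON_NO_SYMBOL = "no gene symbol"
REASON_NO_EC = "no EC"


@dataclass
class EnzymeMap:
    """Layered identifier map: probeset -> UniGene -> gene symbol -> EC set.

    Each layer is a partial map; entries that fail a layer are reported with
    the failing layer named, never silently dropped.  A gene may carry
    several EC numbers (a multifunctional enzyme); its probesets fan out to
    every EC.
    """

    probeset_to_unigene: dict[str, str]
    unigene_to_symbol: dict[str, str]
    symbol_to_ecs: dict[str, frozenset[str]]

    @classmethod
    def from_tables(
        cls,
        probeset_unigene: pd.DataFrame,
        unigene_symbol: pd.DataFrame,
        symbol_ec: pd.DataFrame,
    ) -> "EnzymeMap":
        """Build from the three annotation TSV layers (one pair per row).

        Column order is positional: (child id, parent id).  Duplicate rows
        are tolerated when consistent; a probeset listed with two different
        UniGene clusters (or a UniGene with two symbols) is a hard error
        listing the offenders.
        """
        p2u = _strict_pairs(probeset_unigene, "probeset", "UniGene")
        u2s = _strict_pairs(unigene_symbol, "UniGene", "gene symbol")
        s2e: dict[str, set[str]] = {}
        for sym, ec in symbol_ec.iloc[:, :2].itertuples(index=False):
            s2e.setdefault(str(sym), set()).add(str(ec))
        return cls(p2u, u2s, {s: frozenset(e) for s, e in s2e.items()})

    def to_tables(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        p2u = pd.DataFrame(sorted(self.probeset_to_unigene.items()), columns=["probeset", "unigene"])
        u2s = pd.DataFrame(sorted(self.unigene_to_symbol.items()), columns=["unigene", "symbol"])
        rows = [(s, e) for s, ecs in sorted(self.symbol_to_ecs.items()) for e in sorted(ecs)]
        s2e = pd.DataFrame(rows, columns=["symbol", "ec"])
        return p2u, u2s, s2e

    def all_ecs(self) -> frozenset[str]:
        out: set[str] = set()
        for ecs in self.symbol_to_ecs.values():
            out |= ecs
        return frozenset(out)

    def probeset_symbol(self, probeset: str) -> str | None:
        ug = self.probeset_to_unigene.get(probeset)
        return None if ug is None else self.unigene_to_symbol.get(ug)


def _strict_pairs(df: pd.DataFrame, child: str, parent: str) -> dict[str, str]:
    out: dict[str, str] = {}
    conflicts = []
    for a, b in df.iloc[:, :2].itertuples(index=False):
        a, b = str(a), str(b)
        if a in out and out[a] != b:
            conflicts.append((a, out[a], b))
        out[a] = b
    if conflicts:
        shown = "; ".join(f"{a}: {x!r} vs {y!r}" for a, x, y in conflicts[:10])
        raise ValueError(f"conflicting {child}->{parent} assignments: {shown}")
    return out


def resolve_enzymes(
    emap: EnzymeMap, probesets: Iterable[str]
) -> tuple[dict[str, frozenset[str]], pd.DataFrame]:
    """Map probesets through every layer to EC sets.

    Returns (probeset -> EC-set map over the resolvable probesets, unmapped
    report with columns ``probeset``/``reason`` naming the layer that
    failed).
    """
    mapped: dict[str, frozenset[str]] = {}
    unmapped: list[tuple[str, str]] = []
    for ps in probesets:
        ug = emap.probeset_to_unigene.get(ps)
        if ug is None:
            unmapped.append((ps, REASON_NO_UNIGENE))
            continue
        sym = emap.unigene_to_symbol.get(ug)
        if sym is None:
            unmapped.append((ps, REASON_NO_SYMBOL))
            continue
        ecs = emap.symbol_to_ecs.get(sym)
        if not ecs:
            unmapped.append((ps, REASON_NO_EC))
            continue
        mapped[ps] = ecs
    report = pd.DataFrame(unmapped, columns=["probeset", "reason"])
    if len(report):
        logger.info("resolve_enzymes: %d of %d probesets unmapped", len(report), len(report) + len(mapped))
    return mapped, report


@dataclass
class CollapsedScores:
    """EC-level scores with full provenance of the collapse.

    ``provenance[ec]`` records every contributing probeset; in ``max_abs``
    mode ``chosen[ec]`` names the single probeset whose signed score was
    kept.
    """

    scores: dict[str, float]
    provenance: dict[str, list[str]]
    mode: str
    chosen: dict[str, str] = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        s = pd.Series(self.scores, name="score")
        s.index.name = "ec"
        return s


def collapse_scores(
    probe_scores: Mapping[str, float],
    mapping: Mapping[str, frozenset[str]],
    mode: str = "average",
) -> CollapsedScores:
    """Collapse per-probeset scores to one signed score per EC.

    A probeset contributes to every EC of its gene (fan-out): each catalytic
    activity is a separate node of the network and receives the full
    evidence from the probe.  ``max_abs`` ties (equal magnitude, opposite
    sign) break deterministically toward the lexicographically smallest
    probeset id and are logged.
    """
    if mode not in ("average", "max_abs"):
        raise ValueError(f"unknown collapse mode {mode!r}")
    groups: dict[str, list[str]] = {}
    for ps in sorted(probe_scores):
        for ec in mapping.get(ps, ()):  # unmapped probes are simply skipped
            groups.setdefault(ec, []).append(ps)
    if not groups:
        raise ValueError("nothing to collapse: no scored probeset maps to any EC")
    scores: dict[str, float] = {}
    chosen: dict[str, str] = {}
    for ec, members in groups.items():
        vals = [float(probe_scores[ps]) for ps in members]
        if mode == "average":
            scores[ec] = sum(vals) / len(vals)
        else:
            best_idx = max(range(len(vals)), key=lambda i: (abs(vals[i]), -i))
            ties = [i for i in range(len(vals)) if abs(vals[i]) == abs(vals[best_idx])]
            if len(ties) > 1 and len({vals[i] for i in ties}) > 1:
                logger.info(
                    "max_abs tie on EC %s among %s; keeping %s",
                    ec, [members[i] for i in ties], members[ties[0]],
                )
            best_idx = ties[0]  # lexicographic: members is sorted
            scores[ec] = vals[best_idx]
            chosen[ec] = members[best_idx]
    return CollapsedScores(scores=scores, provenance=groups, mode=mode, chosen=chosen)


def uncovered_ecs(catalog_sets: Mapping[str, frozenset[str]], known_ecs: frozenset[str]) -> dict[str, list[str]]:
    """ECs referenced by a catalog that the map cannot resolve, per pathway."""
    out: dict[str, list[str]] = {}
    for name, members in catalog_sets.items():
        missing = sorted(set(members) - known_ecs)
        if missing:
            out[name] = missing
    return out
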