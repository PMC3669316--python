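"""EC-level gene-set enrichment: SNR ranking, ES/NES, permutation null, FDR.

The ranking metric is the signal-to-noise ratio between the treatment and
control classes,

    s = (mu_t - mu_c) / (sigma_t + sigma_c),

with each class standard deviation floored at ``max(0.2 * |mu|, eps)`` so
that low-variance probes cannot dominate the list.  Probe-level SNR values
are collapsed to Enzyme Commission (EC) activity level (see
:mod:`pathflux.annotation`) and the collapsed, ranked list is scored against
pathway catalogs with the weighted Kolmogorov-Smirnov-like running-sum
statistic: walking down the list, the sum gains ``|s_i|**p / sum_hits
|s_j|**p`` at each set member and loses ``1 / (N - N_hits)`` at each
non-member; the enrichment score ES is the signed maximum deviation from
zero and the leading edge is the set members at or before (after, for
negative ES) the extremum.

Significance comes from a permutation null — either relabelled phenotypes
(ranking and collapse recomputed per permutation) or random same-size EC
sets — with the normalized enrichment score NES = ES / mean(|null ES| of
matching sign), a sign-stratified nominal p with a plus-one rule, and a
sign-stratified null-ratio FDR q.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .annotation import CollapsedScores, EnzymeMap, collapse_scores, resolve_enzymes
from .io import ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = [
    "snr_rank",
    "RankedList",
    "PathwayCatalog",
    "build_catalog",
    "enrichment_score",
    "EnrichmentResult",
    "GseaRun",
    "permutation_significance",
    "heatmap_table",
]

SD_FLOOR_FRACTION = 0.2
SD_FLOOR_EPS = 1e-8
#: below this many samples per class, phenotype permutation is too coarse
MIN_CLASS_FOR_PHENOTYPE = 7


# ---------------------------------------------------------------------------
# SNR ranking

def _class_stats(x: np.ndarray, mask: np.ndarray, floor_frac: float, eps: float):
    """Per-row mean and floored sd over the columns selected by ``mask``."""
    n = int(mask.sum())
    if n < 2:
        raise ValueError(f"class has {n} samples; need >= 2 for a standard deviation")
    sub = x[:, mask]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    sd = np.maximum(sd, np.maximum(floor_frac * np.abs(mu), eps))
    return mu, sd


def snr_rank(
    study: ExpressionStudy,
    floor_frac: float = SD_FLOOR_FRACTION,
    eps: float = SD_FLOOR_EPS,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-probeset signal-to-noise ratio, treatment minus control.

    Returns the score series and an audit frame with the per-class means and
    (floored) standard deviations that produced each score.  Positive scores
    mean higher expression in the treatment class (``study.classes[0]``).
    """
    x = study.values.to_numpy(dtype=float)
    treat = (study.labels == study.classes[0]).to_numpy()
    mu_t, sd_t = _class_stats(x, treat, floor_frac, eps)
    mu_c, sd_c = _class_stats(x, ~treat, floor_frac, eps)
    scores = (mu_t - mu_c) / (sd_t + sd_c)
    idx = study.values.index
    audit = pd.DataFrame(
        {"mu_treat": mu_t, "sd_treat": sd_t, "mu_ctrl": mu_c, "sd_ctrl": sd_c, "snr": scores},
        index=idx,
    )
    return pd.Series(scores, index=idx, name="snr"), audit


@dataclass
class RankedList:
    """EC ids with scores, strictly ordered by (score desc, id asc)."""

    ids: tuple[str, ...]
    scores: np.ndarray
    classes: tuple[str, str] | None = None
    audit: pd.DataFrame | None = None

    @classmethod
    def from_scores(cls, scores: Mapping[str, float], classes=None, audit=None) -> "RankedList":
        items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        ids = tuple(k for k, _ in items)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in ranked list")
        return cls(ids=ids, scores=np.array([v for _, v in items], dtype=float),
                   classes=classes, audit=audit)

    def __len__(self) -> int:
        return len(self.ids)

    def position_of(self) -> dict[str, int]:
        return {i: k for k, i in enumerate(self.ids)}


# ---------------------------------------------------------------------------
# Pathway catalogs

@dataclass
class PathwayCatalog:
    """Named EC sets; merged ("artificial") pathways carry their provenance."""

    sets: dict[str, frozenset[str]]
    flags: dict[str, str] = field(default_factory=dict)  # native | merged
    provenance: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        for name in self.sets:
            self.flags.setdefault(name, "native")

    def native_union(self) -> frozenset[str]:
        out: set[str] = set()
        for name, members in self.sets.items():
            if self.flags.get(name) == "native":
                out |= members
        return frozenset(out)

    def __iter__(self):
        return iter(self.sets)

    def __len__(self):
        return len(self.sets)


def build_catalog(
    native: Mapping[str, Iterable[str]],
    merges: Mapping[str, Sequence[str]] | None = None,
    all_union: str | None = None,
) -> PathwayCatalog:
    """Assemble a catalog of native pathways plus merged artificial ones.

    A merged pathway is the union of its member pathways with duplicates
    removed; ``all_union`` adds one pathway holding the non-redundant union
    of every native set.
    """
    sets = {name: frozenset(members) for name, members in native.items()}
    flags = {name: "native" for name in sets}
    provenance: dict[str, tuple[str, ...]] = {}
    for name, members in (merges or {}).items():
        unknown = [m for m in members if m not in native]
        if unknown:
            raise ValueError(f"merged pathway {name!r} references unknown pathways: {unknown}")
        if name in sets:
            raise ValueError(f"merged pathway name {name!r} collides with a native pathway")
        merged: set[str] = set()
        for m in members:
            merged |= sets[m]
        sets[name] = frozenset(merged)
        flags[name] = "merged"
        provenance[name] = tuple(members)
    if all_union is not None:
        if all_union in sets:
            raise ValueError(f"all-union name {all_union!r} collides with an existing pathway")
        union: set[str] = set()
        for name in native:
            union |= sets[name]
        sets[all_union] = frozenset(union)
        flags[all_union] = "merged"
        provenance[all_union] = tuple(native)
    return PathwayCatalog(sets=sets, flags=flags, provenance=provenance)


# ---------------------------------------------------------------------------
# Enrichment score

def _scan_es(scores: np.ndarray, is_hit: np.ndarray, p: float):
    """Full running-sum scan; returns (es, profile, extremum index)."""
    n = scores.size
    n_hit = int(is_hit.sum())
    if n_hit == 0:
        raise ValueError("set is disjoint from the ranked list")
    if n_hit == n:
        raise ValueError("set equals the entire ranked list; miss step undefined")
    w = np.where(is_hit, np.abs(scores) ** p, 0.0)
    total = w.sum()
    if total <= 0:  # all hit scores exactly zero: fall back to unweighted hits
        w = is_hit.astype(float)
        total = float(n_hit)
    steps = np.where(is_hit, w / total, -1.0 / (n - n_hit))
    profile = np.cumsum(steps)
    i_top = int(np.argmax(profile))
    i_bot = int(np.argmin(profile))
    # |max| == |min| ties (to within float noise) resolve toward the positive
    # extremum, so both ES evaluation routes agree on the sign
    i = i_top if profile[i_top] >= -profile[i_bot] - 1e-12 else i_bot
    # the statistic is bounded by [-1, 1]; trim float accumulation overshoot
    return float(np.clip(profile[i], -1.0, 1.0)), profile, i


def enrichment_score(
    ranked: RankedList, pathway_set: Iterable[str], p: float = 1.0
) -> tuple[float, np.ndarray, tuple[str, ...]]:
    """Weighted running-sum enrichment score of one EC set on a ranked list.

    Returns ``(ES, running-sum profile, leading edge)``.  The leading edge
    is the set members at or before the running-sum extremum for positive
    ES, and at or after it for negative ES.
    """
    members = frozenset(pathway_set)
    is_hit = np.fromiter((i in members for i in ranked.ids), dtype=bool, count=len(ranked))
    es, profile, i = _scan_es(ranked.scores, is_hit, p)
    if es >= 0:
        edge_idx = np.nonzero(is_hit[: i + 1])[0]
    else:
        edge_idx = i + np.nonzero(is_hit[i:])[0]
    leading = tuple(ranked.ids[j] for j in edge_idx)
    return es, profile, leading


def _es_from_hit_ranks(ranks: np.ndarray, weights: np.ndarray, n_total: int) -> np.ndarray:
    """Enrichment scores from hit positions only; columns are instances.

    ``ranks`` is (k, m), ascending 0-based positions of the k set members in
    each of m ranked lists; ``weights`` the matching |score|**p values.
    Equivalent to the full scan but O(k) per instance: the maximum of the
    running sum is attained at a hit and the minimum just before a hit.
    """
    k, m = ranks.shape
    n_miss = n_total - k
    if n_miss <= 0:
        raise ValueError("set equals the entire ranked list")
    total = weights.sum(axis=0)
    degenerate = total <= 0
    if np.any(degenerate):
        weights = weights.copy()
        weights[:, degenerate] = 1.0
        total = weights.sum(axis=0)
    cum = np.cumsum(weights, axis=0) / total
    j = np.arange(1, k + 1, dtype=float)[:, None]
    after = cum - (ranks + 1.0 - j) / n_miss
    before = (cum - weights / total) - (ranks - (j - 1.0)) / n_miss
    top = after.max(axis=0)
    bot = before.min(axis=0)
    return np.clip(np.where(top >= -bot - 1e-12, top, bot), -1.0, 1.0)


# ---------------------------------------------------------------------------
# Permutation significance

@dataclass
class EnrichmentResult:
    """Per-pathway enrichment summary."""

    pathway: str
    size: int
    es: float
    nes: float
    p: float
    q: float
    leading_edge: tuple[str, ...]
    scheme: str
    n_perm: int


@dataclass
class GseaRun:
    """Ordered enrichment results plus the run metadata that produced them."""

    results: list[EnrichmentResult]
    metadata: dict
    skipped: dict[str, str] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "pathway": r.pathway, "size": r.size, "es": r.es, "nes": r.nes,
                "p": r.p, "q": r.q, "leading_edge": ";".join(r.leading_edge),
            }
            for r in self.results
        ]
        return pd.DataFrame(rows, columns=["pathway", "size", "es", "nes", "p", "q", "leading_edge"])


def _resolve_scheme(scheme: str, min_class: int, allow_small_phenotype: bool) -> str:
    if scheme == "auto":
        return "phenotype" if min_class >= MIN_CLASS_FOR_PHENOTYPE else "set"
    if scheme == "phenotype" and min_class < MIN_CLASS_FOR_PHENOTYPE and not allow_small_phenotype:
        logger.warning(
            "phenotype permutation requested with %d samples in the smaller class "
            "(< %d); falling back to set permutation", min_class, MIN_CLASS_FOR_PHENOTYPE,
        )
        return "set"
    return scheme


def _set_scheme_nulls(
    rng: np.random.Generator, scores: np.ndarray, sizes: Iterable[int], n_perm: int, p: float
) -> dict[int, np.ndarray]:
    """Null ES distributions from random same-size sets, one per distinct size."""
    n = scores.size
    absw = np.abs(scores) ** p
    out: dict[int, np.ndarray] = {}
    for k in sorted(set(sizes)):
        u = rng.random((n_perm, n))
        pos = np.argpartition(u, k, axis=1)[:, :k]  # k random distinct positions per row
        pos.sort(axis=1)
        out[k] = _es_from_hit_ranks(pos.T.astype(float), absw[pos].T, n)
    return out


def _phenotype_nulls(
    rng: np.random.Generator,
    study: ExpressionStudy,
    collapsed: CollapsedScores,
    ec_ids: Sequence[str],
    member_positions: Mapping[str, np.ndarray],
    n_perm: int,
    p: float,
    floor_frac: float,
    eps: float,
) -> dict[str, np.ndarray]:
    """Null ES per pathway from relabelled phenotypes.

    The SNR ranking and the EC collapse are recomputed for every
    permutation; only the probe->EC mapping is fixed.
    """
    x = study.values.to_numpy(dtype=float)
    n_probe, n_samp = x.shape
    n1 = int((study.labels == study.classes[0]).sum())

    masks = np.zeros((n_samp, n_perm))
    for b in range(n_perm):
        masks[rng.permutation(n_samp)[:n1], b] = 1.0
    n2 = n_samp - n1

    x2 = x * x
    s1, s2 = x @ masks, x @ (1.0 - masks)
    q1, q2 = x2 @ masks, x2 @ (1.0 - masks)
    m1, m2 = s1 / n1, s2 / n2
    v1 = np.maximum(q1 - n1 * m1 * m1, 0.0) / (n1 - 1)
    v2 = np.maximum(q2 - n2 * m2 * m2, 0.0) / (n2 - 1)
    sd1 = np.maximum(np.sqrt(v1), np.maximum(floor_frac * np.abs(m1), eps))
    sd2 = np.maximum(np.sqrt(v2), np.maximum(floor_frac * np.abs(m2), eps))
    snr = (m1 - m2) / (sd1 + sd2)  # (n_probe, n_perm)

    # average-collapse matrix in ec_ids order
    probe_pos = {ps: i for i, ps in enumerate(study.values.index)}
    rows, cols, vals = [], [], []
    for e, ec in enumerate(ec_ids):
        probes = collapsed.provenance[ec]
        for ps in probes:
            rows.append(e)
            cols.append(probe_pos[ps])
            vals.append(1.0 / len(probes))
    amat = sp.csr_matrix((vals, (rows, cols)), shape=(len(ec_ids), n_probe))
    ec_scores = amat @ snr  # (n_ec, n_perm)

    order = np.argsort(-ec_scores, axis=0, kind="stable")
    inv = np.empty_like(order)
    np.put_along_axis(inv, order, np.arange(len(ec_ids))[:, None], axis=0)

    nulls: dict[str, np.ndarray] = {}
    n_ec = len(ec_ids)
    for name, idx in member_positions.items():
        ranks = inv[idx, :].astype(float)           # (k, n_perm)
        w = np.abs(ec_scores[idx, :]) ** p
        ordarg = np.argsort(ranks, axis=0)
        ranks = np.take_along_axis(ranks, ordarg, axis=0)
        w = np.take_along_axis(w, ordarg, axis=0)
        nulls[name] = _es_from_hit_ranks(ranks, w, n_ec)
    return nulls


def _nes_and_p(es: float, nulls: np.ndarray) -> tuple[float, float]:
    """Sign-stratified NES and nominal p (plus-one rule, never zero)."""
    if es >= 0:
        same = nulls[nulls > 0]
        extreme = int((same >= es).sum())
    else:
        same = nulls[nulls < 0]
        extreme = int((same <= es).sum())
    if same.size == 0:
        return float("nan"), 1.0
    nes = es / float(np.mean(np.abs(same)))
    p = (1.0 + extreme) / (1.0 + same.size)
    return nes, p


def _fdr_q(obs_nes: np.ndarray, null_nes_pool: np.ndarray) -> np.ndarray:
    """Sign-stratified null-ratio FDR q, monotone within each sign stratum."""
    q = np.ones_like(obs_nes)
    finite_obs = obs_nes[np.isfinite(obs_nes)]
    pool = null_nes_pool[np.isfinite(null_nes_pool)]
    for sign in (1, -1):
        idx = np.nonzero(np.isfinite(obs_nes) & ((obs_nes >= 0) if sign > 0 else (obs_nes < 0)))[0]
        if idx.size == 0:
            continue
        n_null_side = int((pool >= 0).sum()) if sign > 0 else int((pool < 0).sum())
        n_obs_side = int((finite_obs >= 0).sum()) if sign > 0 else int((finite_obs < 0).sum())
        for i in idx:
            v = obs_nes[i]
            if sign > 0:
                num = (pool >= v).sum() / n_null_side if n_null_side else 1.0
                den = (finite_obs >= v).sum() / n_obs_side
            else:
                num = (pool <= v).sum() / n_null_side if n_null_side else 1.0
                den = (finite_obs <= v).sum() / n_obs_side
            q[i] = min(1.0, num / den) if den > 0 else 1.0
        # enforce: more extreme NES never has larger q
        order = idx[np.argsort(-np.abs(obs_nes[idx]), kind="stable")]
        q[order] = np.minimum.accumulate(q[order][::-1])[::-1]
    return q


def permutation_significance(
    study: ExpressionStudy,
    emap: EnzymeMap,
    catalog: PathwayCatalog,
    *,
    scheme: str = "auto",
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
    floor_frac: float = SD_FLOOR_FRACTION,
    eps: float = SD_FLOOR_EPS,
    allow_small_phenotype: bool = False,
) -> GseaRun:
    """Score every catalog pathway on the EC-collapsed SNR ranking.

    Probes are ranked by SNR, collapsed to EC level by average, and each
    pathway's ES is referred to a permutation null (``phenotype`` or
    ``set`` scheme; ``auto`` picks phenotype when both classes have at
    least seven samples).  Results are ordered by NES descending.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if scheme not in ("auto", "phenotype", "set"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    rng = np.random.default_rng(seed)

    snr, _audit = snr_rank(study, floor_frac, eps)
    mapping, unmapped = resolve_enzymes(emap, study.values.index)
    collapsed = collapse_scores(snr.to_dict(), mapping, "average")
    ranked = RankedList.from_scores(collapsed.scores, classes=study.classes)
    pos = ranked.position_of()
    n_ec = len(ranked)

    kept: dict[str, np.ndarray] = {}
    skipped: dict[str, str] = {}
    for name, members in catalog.sets.items():
        inter = sorted(m for m in members if m in pos)
        if not inter:
            skipped[name] = "disjoint from ranked list"
        elif len(inter) < min_size:
            skipped[name] = f"size {len(inter)} < min_size {min_size}"
        elif len(inter) > max_size:
            skipped[name] = f"size {len(inter)} > max_size {max_size}"
        elif len(inter) == n_ec:
            skipped[name] = "covers the entire ranked list"
        else:
            kept[name] = np.array([pos[m] for m in inter], dtype=int)
    for name, why in skipped.items():
        logger.info("skipping pathway %r: %s", name, why)
    if not kept:
        raise ValueError("no pathway passed the size filters")

    min_class = min(study.n_samples_per_class.values())
    used_scheme = _resolve_scheme(scheme, min_class, allow_small_phenotype)

    observed: dict[str, tuple[float, tuple[str, ...]]] = {}
    for name, idx in kept.items():
        es, _profile, edge = enrichment_score(ranked, [ranked.ids[i] for i in idx], weight)
        observed[name] = (es, edge)

    if used_scheme == "set":
        by_size = _set_scheme_nulls(rng, ranked.scores, (len(i) for i in kept.values()), n_perm, weight)
        nulls = {name: by_size[len(idx)] for name, idx in kept.items()}
    else:
        nulls = _phenotype_nulls(
            rng, study, collapsed, ranked.ids, kept, n_perm, weight, floor_frac, eps
        )

    names = list(kept)
    nes_arr = np.empty(len(names))
    p_arr = np.empty(len(names))
    null_nes_parts = []
    for i, name in enumerate(names):
        es, _edge = observed[name]
        nes_arr[i], p_arr[i] = _nes_and_p(es, nulls[name])
        arr = nulls[name]
        pos_mean = np.abs(arr[arr > 0]).mean() if (arr > 0).any() else np.nan
        neg_mean = np.abs(arr[arr < 0]).mean() if (arr < 0).any() else np.nan
        normed = np.where(arr >= 0, arr / pos_mean, arr / neg_mean)
        null_nes_parts.append(normed[np.isfinite(normed)])
    q_arr = _fdr_q(nes_arr, np.concatenate(null_nes_parts))

    results = [
        EnrichmentResult(
            pathway=name,
            size=len(kept[name]),
            es=observed[name][0],
            nes=float(nes_arr[i]),
            p=float(p_arr[i]),
            q=float(q_arr[i]),
            leading_edge=observed[name][1],
            scheme=used_scheme,
            n_perm=n_perm,
        )
        for i, name in enumerate(names)
    ]
    results.sort(key=lambda r: (-(r.nes if np.isfinite(r.nes) else -np.inf), r.pathway))
    metadata = {
        "seed": seed,
        "scheme": used_scheme,
        "requested_scheme": scheme,
        "n_perm": n_perm,
        "weight": weight,
        "min_size": min_size,
        "max_size": max_size,
        "n_ecs_ranked": n_ec,
        "n_probes_unmapped": int(len(unmapped)),
        "fdr": "sign-stratified null-ratio q",
        "classes": tuple(study.classes),
    }
    return GseaRun(results=results, metadata=metadata, skipped=skipped)


# ---------------------------------------------------------------------------
# Heat-map tables

def heatmap_table(
    study: ExpressionStudy,
    emap: EnzymeMap,
    catalog: PathwayCatalog,
    pathway: str,
    floor_frac: float = SD_FLOOR_FRACTION,
    eps: float = SD_FLOOR_EPS,
) -> pd.DataFrame:
    """Per-enzyme table for one pathway, collapse forced to max-abs SNR.

    One row per EC with a mapped, scored probeset: the signed SNR of the
    constituent probeset with the largest absolute SNR, plus that probeset
    and its gene symbol as provenance.  Rows sorted by SNR descending.
    """
    if pathway not in catalog.sets:
        raise KeyError(f"pathway {pathway!r} not in catalog")
    snr, _ = snr_rank(study, floor_frac, eps)
    mapping, _ = resolve_enzymes(emap, study.values.index)
    members = catalog.sets[pathway]
    sub = {ps: frozenset(e for e in ecs if e in members) for ps, ecs in mapping.items()}
    sub = {ps: ecs for ps, ecs in sub.items() if ecs}
    cols = ["ec", "snr", "probeset", "gene_symbol"]
    if not sub:
        logger.warning("pathway %r has no mapped members in this study", pathway)
        return pd.DataFrame(columns=cols)
    collapsed = collapse_scores(snr.to_dict(), sub, "max_abs")
    rows = []
    for ec, score in collapsed.scores.items():
        ps = collapsed.chosen[ec]
        rows.append({"ec": ec, "snr": score, "probeset": ps,
                     "gene_symbol": emap.probeset_symbol(ps) or ""})
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["snr", "ec"], ascending=[False, True], kind="stable").reset_index(drop=True)
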