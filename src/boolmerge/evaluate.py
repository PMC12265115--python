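"""Model comparison and scoring.

Attractors are compared through their *patterns* — per-gene mean
activations over the attractor's states (a fixed point gives a 0/1 vector,
a cyclic attractor a fractional one).  Patterns are clustered by mean
absolute difference (normalized Hamming distance) with average linkage.

The phenotype network score connects the model to clinical readouts:
phenotype expressions for proliferation, apoptosis and differentiation are
evaluated on every attractor state and combined as

    score = proliferation - apoptosis - differentiation

(bounded in [-2, 1]); higher scores proxy more proliferative, less
differentiated behavior.  Patient cohorts are scored by clamping each
mutation profile (gain of function -> 1, loss of function -> 0), recomputing
attractors and averaging the score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, spearmanr

from .logic import BoolExpr, evaluate as eval_expr, parse_rule, variables
from .model import LogicalModel, MutationProfile
from .dynamics import ASYNC, Attractor, attractors as find_attractors, clamp

__all__ = [
    "PhenotypeSpec",
    "MutationProfile",
    "hamming_distance",
    "cluster_attractors",
    "network_score",
    "cohort_scores",
    "correlate",
    "attractor_retention",
]


@dataclass
class PhenotypeSpec:
    """Phenotype read-out expressions over model nodes."""

    proliferation: BoolExpr
    apoptosis: BoolExpr
    differentiation: BoolExpr

    @classmethod
    def from_rules(
        cls, proliferation: str, apoptosis: str, differentiation: str
    ) -> "PhenotypeSpec":
        return cls(
            parse_rule(proliferation),
            parse_rule(apoptosis),
            parse_rule(differentiation),
        )

    @classmethod
    def from_dict(cls, payload: Mapping[str, str]) -> "PhenotypeSpec":
        return cls.from_rules(
            payload["proliferation"],
            payload["apoptosis"],
            payload["differentiation"],
        )

    def validate_for(self, model: LogicalModel) -> None:
        for name in ("proliferation", "apoptosis", "differentiation"):
            expr = getattr(self, name)
            missing = sorted(variables(expr) - set(model.node_ids()))
            if missing:
                raise ValueError(
                    f"phenotype {name!r} references nodes absent from the "
                    f"model: {missing}"
                )


# ---------------------------------------------------------------------------
# attractor-pattern comparison


def hamming_distance(
    a: Mapping[str, float],
    b: Mapping[str, float],
    genes: Sequence[str] | None = None,
) -> float:
    """Mean absolute difference of two attractor patterns over shared genes.

    Patterns are per-gene mean activations in [0, 1] (see
    :meth:`Attractor.mean_activation`); the distance is therefore in [0, 1]
    and reduces to the normalized Hamming distance on fixed points.
    """
    if genes is None:
        genes = sorted(set(a) & set(b))
    genes = list(genes)
    if not genes:
        raise ValueError("no shared genes to compare patterns on")
    return float(np.mean([abs(a[g] - b[g]) for g in genes]))


def cluster_attractors(
    patterns: Sequence[tuple[str, Mapping[str, float]]],
    threshold: float = 0.5,
    method: str = "average",
) -> tuple[np.ndarray, dict[str, int]]:
    """Agglomerative clustering of attractor patterns by Hamming distance.

    ``patterns`` is a sequence of ``(label, pattern)`` pairs; patterns may
    cover different gene sets (pairwise distances use pairwise-shared
    genes).  Returns the scipy linkage matrix and a ``label -> cluster id``
    assignment at the distance ``threshold``.  Ties are broken by input
    (label) order, which scipy's deterministic linkage preserves.
    """
    if len(patterns) < 2:
        raise ValueError("clustering requires at least two patterns")
    labels = [lab for lab, _ in patterns]
    k = len(patterns)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = hamming_distance(patterns[i][1], patterns[j][1])
            dist[i, j] = dist[j, i] = d
    z = linkage(squareform(dist, checks=False), method=method)
    flat = fcluster(z, t=threshold, criterion="distance")
    return z, dict(zip(labels, (int(c) for c in flat)))


# ---------------------------------------------------------------------------
# phenotype network score


def _state_score(spec: PhenotypeSpec, state: Mapping[str, int]) -> int:
    return (
        eval_expr(spec.proliferation, state)
        - eval_expr(spec.apoptosis, state)
        - eval_expr(spec.differentiation, state)
    )


def network_score(
    model: LogicalModel,
    phenotypes: PhenotypeSpec,
    attrs: Sequence[Attractor],
    mode: str = "mean",
) -> float | dict[str, float]:
    """Phenotype score of a model over its attractors.

    Per state: proliferation - apoptosis - differentiation (each 0/1).  An
    attractor scores the mean over its states; ``mode="mean"`` returns the
    mean over attractors (in [-2, 1]); ``mode="per_attractor"`` returns a
    ``label -> score`` mapping instead.
    """
    phenotypes.validate_for(model)
    if not attrs:
        raise ValueError("network_score requires at least one attractor")
    per = {
        a.label: float(
            np.mean([_state_score(phenotypes, s) for s in a.states])
        )
        for a in attrs
    }
    if mode == "per_attractor":
        return per
    if mode != "mean":
        raise ValueError(f"unknown mode {mode!r}")
    return float(np.mean(list(per.values())))


def cohort_scores(
    model: LogicalModel,
    phenotypes: PhenotypeSpec,
    profiles: Sequence[MutationProfile],
    scheme: str = ASYNC,
    mode: str = "exact",
    seed: int | None = None,
) -> pd.DataFrame:
    """Score a cohort of mutation profiles.

    Profile genes absent from the model are dropped with a warning and
    counted per profile.  Identical (restricted) profiles are computed once
    and weighted by the number of patients carrying them.  Returns one row
    per distinct profile: ``profile``, ``n`` (patients), ``score``,
    ``dropped_genes``.
    """
    known = set(model.node_ids())
    groups: dict[tuple, dict] = {}
    for p in profiles:
        kept = {g: e for g, e in p.effects.items() if g in known}
        dropped = sorted(set(p.effects) - known)
        if dropped:
            warnings.warn(
                f"profile {p.profile_id or '?'}: dropping genes not in the "
                f"model: {dropped}",
                stacklevel=2,
            )
        key = tuple(sorted(kept.items()))
        grp = groups.setdefault(
            key,
            {"effects": kept, "n": 0, "ids": [], "dropped": len(dropped)},
        )
        grp["n"] += 1
        if p.profile_id:
            grp["ids"].append(p.profile_id)

    rows = []
    for key, grp in sorted(groups.items()):
        restricted = MutationProfile(dict(grp["effects"]))
        clamped = clamp(model, restricted)
        attrs = find_attractors(clamped, scheme=scheme, mode=mode, seed=seed)
        score = network_score(clamped, phenotypes, attrs)
        name = ";".join(f"{g}:{e}" for g, e in key) or "wild_type"
        rows.append((name, grp["n"], score, grp["dropped"]))
    return pd.DataFrame(
        rows, columns=["profile", "n", "score", "dropped_genes"]
    )


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "pearson",
    weights: Sequence[int] | None = None,
) -> float:
    """Correlation between model scores and an outcome variable.

    ``weights`` are integer multiplicities (e.g. patients per mutation
    profile); weighted correlation is computed by frequency expansion.
    Raises on zero variance (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if x.size < 3:
        raise ValueError("correlation requires at least 3 observations")
    if weights is not None:
        w = np.asarray(weights)
        if w.shape != x.shape or (w <= 0).any():
            raise ValueError("weights must be positive and match x")
        x = np.repeat(x, w)
        y = np.repeat(y, w)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        return float(pearsonr(x, y).statistic)
    if method == "spearman":
        return float(spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def attractor_retention(
    original: Sequence[Attractor],
    merged: Sequence[Attractor],
    genes: Sequence[str],
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Functionality-retention report: for each original attractor, the
    nearest merged attractor on the shared genes.

    One row per original attractor: label, nearest merged label, distance,
    and whether the distance is within ``threshold``.  A merged model
    retains the original's behavior when every row is retained.
    """
    rows = []
    genes = list(genes)
    for a in original:
        pa = a.mean_activation()
        best_label, best_d = None, np.inf
        for b in merged:
            d = hamming_distance(pa, b.mean_activation(), genes)
            if d < best_d:
                best_label, best_d = b.label, d
        rows.append((a.label, best_label, best_d, best_d <= threshold))
    return pd.DataFrame(
        rows, columns=["original", "nearest_merged", "distance", "retained"]
    )
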