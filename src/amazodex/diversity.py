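"""Diversity statistics on incidence (presence/absence) matrices.

An incidence matrix records which species occur in which sampling units
(sub-basins, grid cells, or years treated as samples).  From it we
compute observed richness and endemism per unit, Jaccard compositional
similarity with average-linkage (UPGMA) clustering, exact and
permutation species-accumulation curves, and first/second-order
incidence-based jackknife richness estimators.  A Poisson GLM relates
per-basin richness to basin area.

Notation: m sampling units; m_i units occupied by species i; Q1, Q2 the
numbers of species found in exactly one / exactly two units; S_obs the
number of species with at least one incidence.  The second-order
jackknife is

    S_hat = S_obs + Q1 (2m - 3) / m - Q2 (m - 2)^2 / (m (m - 1)).

The exact accumulation curve is the hypergeometric expectation

    E[S(t)] = sum_i [ 1 - C(m - m_i, t) / C(m, t) ].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .core import OccurrenceRecord, Taxonomy

__all__ = [
    "IncidenceMatrix",
    "Dendrogram",
    "build_incidence",
    "incidence_by_year",
    "richness_endemism",
    "jaccard_similarity",
    "upgma_cluster",
    "cut",
    "accumulation_curve",
    "jackknife1",
    "jackknife2",
    "poisson_glm",
]


class IncidenceMatrix:
    """Sampling-unit x species presence/absence table."""

    def __init__(self, presence: pd.DataFrame):
        self.presence = presence.astype(bool)
        self.presence = self.presence.loc[sorted(presence.index), sorted(presence.columns)]

    @property
    def units(self) -> list:
        return list(self.presence.index)

    @property
    def species(self) -> list:
        return list(self.presence.columns)

    @property
    def m(self) -> int:
        """Number of sampling units."""
        return self.presence.shape[0]

    @property
    def m_i(self) -> pd.Series:
        """Per-species incidence counts (units occupied)."""
        return self.presence.sum(axis=0)

    @property
    def Q1(self) -> int:
        return int((self.m_i == 1).sum())

    @property
    def Q2(self) -> int:
        return int((self.m_i == 2).sum())

    @property
    def S_obs(self) -> int:
        return int((self.m_i >= 1).sum())

    def unit_species(self, unit) -> set:
        row = self.presence.loc[unit]
        return set(row.index[row])


@dataclass
class Dendrogram:
    """Agglomerative merge list: (child_a, child_b, height) triples.

    Children are leaf indices 0..n-1 or prior merge indices n, n+1, ...
    (scipy linkage convention).  Heights are cophenetic distances.
    """

    merges: list[tuple[int, int, float]]
    leaves: list = field(default_factory=list)

    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]


def build_incidence(
    assignments: dict[str, str],
    records: Iterable[OccurrenceRecord],
    unit_ids: Optional[Iterable] = None,
) -> IncidenceMatrix:
    """Presence is true iff >= 1 record of the species in the unit.

    ``unit_ids`` optionally forces empty units into the matrix.
    """
    pairs = set()
    species = set()
    units = set(unit_ids) if unit_ids is not None else set()
    for rec in records:
        unit = assignments.get(rec.record_id)
        if unit is None:
            continue
        name = rec.accepted_name or rec.raw_name
        pairs.add((unit, name))
        species.add(name)
        units.add(unit)
    presence = pd.DataFrame(False, index=sorted(units), columns=sorted(species))
    for unit, name in pairs:
        presence.loc[unit, name] = True
    return IncidenceMatrix(presence)


def incidence_by_year(records: Iterable[OccurrenceRecord]) -> IncidenceMatrix:
    """Years-as-samples incidence matrix; records without a year are excluded."""
    dated = [r for r in records if r.year is not None]
    assignments = {r.record_id: r.year for r in dated}
    return build_incidence(assignments, dated)


def richness_endemism(
    matrix: IncidenceMatrix, taxonomy: Taxonomy, target_code: str = "AM"
) -> pd.DataFrame:
    """Per-unit observed richness and endemic richness.

    A species is endemic when its documented distribution is exactly the
    target biome (code set == {target_code}).
    """
    endemics = {
        sp
        for sp in matrix.species
        if (entry := taxonomy.get(sp)) is not None and entry.biome_codes == {target_code}
    }
    endemic_cols = [sp for sp in matrix.species if sp in endemics]
    out = pd.DataFrame(
        {
            "richness": matrix.presence.sum(axis=1).astype(int),
            "endemic_count": matrix.presence[endemic_cols].sum(axis=1).astype(int),
        },
        index=matrix.units,
    )
    return out


def jaccard_similarity(matrix: IncidenceMatrix) -> pd.DataFrame:
    """Pairwise Jaccard similarity between units: |A ∩ B| / |A ∪ B|.

    Defined as 1 when both unit compositions are empty (with a warning);
    symmetric with a unit diagonal.
    """
    if matrix.m < 2:
        raise ValueError("need at least two units for pairwise similarity")
    p = matrix.presence.to_numpy(dtype=float)
    inter = p @ p.T
    sizes = p.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    if (sizes == 0).any():
        warnings.warn("empty unit composition: J(empty, empty) defined as 1", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=matrix.units, columns=matrix.units)


def upgma_cluster(similarity: pd.DataFrame) -> Dendrogram:
    """Average-linkage (UPGMA) clustering on distance 1 - J.

    Merge heights are non-decreasing (UPGMA monotonicity).
    """
    dist = 1.0 - similarity.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="average")
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
    return Dendrogram(merges=merges, leaves=list(similarity.index))


def cut(dendrogram: Dendrogram, min_similarity: float = 0.40) -> list[set]:
    """Groups of leaves connected by merges at distance < 1 - min_similarity."""
    threshold = 1.0 - min_similarity
    n = len(dendrogram.leaves)
    parent = list(range(2 * n - 1))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for k, (a, b, h) in enumerate(dendrogram.merges):
        node = n + k
        if h < threshold:
            parent[find(a)] = node
            parent[find(b)] = node
        # even above threshold the node exists, but its children stay separate
    groups: dict[int, set] = {}
    for i, leaf in enumerate(dendrogram.leaves):
        groups.setdefault(find(i), set()).add(leaf)
    return sorted(groups.values(), key=lambda g: sorted(map(str, g)))


def accumulation_curve(
    matrix: IncidenceMatrix,
    method: str = "exact",
    n_perm: int = 100,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Expected species richness after t = 1..m sampling units.

    method="exact": closed-form hypergeometric expectation.
    method="permutation": mean (with 2.5 / 97.5 % quantiles) over
    ``n_perm`` random orderings of the units.
    The curve is non-decreasing and ends at S_obs.
    """
    m = matrix.m
    if m < 1:
        raise ValueError("empty incidence matrix")
    if method == "exact":
        m_i = matrix.m_i.to_numpy()
        rows = []
        for t in range(1, m + 1):
            denom = math.comb(m, t)
            expected = sum(1.0 - math.comb(m - mi, t) / denom for mi in m_i if mi > 0)
            rows.append({"t": t, "richness": expected})
        return pd.DataFrame(rows)
    if method == "permutation":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        p = matrix.presence.to_numpy()
        curves = np.empty((n_perm, m))
        for k in range(n_perm):
            order = rng.permutation(m)
            seen = np.cumsum(p[order], axis=0) > 0
            curves[k] = seen.sum(axis=1)
        return pd.DataFrame(
            {
                "t": np.arange(1, m + 1),
                "richness": curves.mean(axis=0),
                "q025": np.quantile(curves, 0.025, axis=0),
                "q975": np.quantile(curves, 0.975, axis=0),
            }
        )
    raise ValueError(f"unknown method {method!r}")


def jackknife1(matrix: IncidenceMatrix) -> float:
    """First-order incidence-based jackknife: S_obs + Q1 (m-1)/m."""
    m = matrix.m
    if m < 1:
        raise ValueError("empty incidence matrix")
    return matrix.S_obs + matrix.Q1 * (m - 1) / m


def jackknife2(matrix: IncidenceMatrix) -> float:
    """Second-order incidence-based jackknife richness estimator."""
    m = matrix.m
    if m < 2:
        raise ValueError("jackknife2 undefined for fewer than two sampling units")
    return (
        matrix.S_obs
        + matrix.Q1 * (2 * m - 3) / m
        - matrix.Q2 * (m - 2) ** 2 / (m * (m - 1))
    )


@dataclass
class GlmFit:
    intercept: float
    slope: float
    z_intercept: float
    z_slope: float
    covariate: str
    converged: bool


def poisson_glm(
    richness: Iterable[float],
    area_km2: Iterable[float],
    covariate: str = "log_area",
) -> GlmFit:
    """Poisson log-link GLM of per-unit richness on area.

    Fitted by IRLS (statsmodels) to tight tolerance; z statistics come
    from the observed information.  ``covariate`` is "log_area"
    (default) or "area" for the raw value.
    """
    import statsmodels.api as sm

    y = np.asarray(list(richness), dtype=float)
    area = np.asarray(list(area_km2), dtype=float)
    if y.size < 3:
        raise ValueError("need at least three units")
    if (area <= 0).any():
        raise ValueError("areas must be positive")
    if covariate == "log_area":
        x = np.log(area)
    elif covariate == "area":
        x = area
    else:
        raise ValueError(f"unknown covariate {covariate!r}")
    X = sm.add_constant(x, has_constant="add")
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(maxiter=100, tol=1e-10)
    if not res.converged:
        raise RuntimeError(f"IRLS did not converge in 100 iterations: {res.mle_retvals}")
    return GlmFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        z_intercept=float(res.params[0] / res.bse[0]),
        z_slope=float(res.params[1] / res.bse[1]),
        covariate=covariate,
        converged=bool(res.converged),
    )


def dendrogram_to_newick(dendrogram: Dendrogram) -> str:
    """Serialize a dendrogram as a Newick string (branch lengths = heights / 2)."""
    n = len(dendrogram.leaves)
    height: dict[int, float] = {i: 0.0 for i in range(n)}
    text: dict[int, str] = {i: str(dendrogram.leaves[i]) for i in range(n)}
    for k, (a, b, h) in enumerate(dendrogram.merges):
        node = n + k
        la = (h - height[a]) / 2.0
        lb = (h - height[b]) / 2.0
        text[node] = f"({text[a]}:{la:.6g},{text[b]}:{lb:.6g})"
        height[node] = h
    root = n + len(dendrogram.merges) - 1 if dendrogram.merges else 0
    return text[root] + ";"
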