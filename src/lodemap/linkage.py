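"""Phase-known two-point linkage analysis and map construction.

The analysis walks the classical outbred full-sib route: grandparent-traced
pedigrees let each heterozygous parent's alleles be assigned a grandparental
origin, turning every parent-to-progeny transmission into an informative
meiosis wherever both the phase and the transmitted allele are unambiguous.
Recombination fractions are estimated per marker pair by direct counting
(theta_hat = R/N, the phase-known MLE), support is the standard two-point
LOD, and cM distances use the Kosambi mapping function throughout.

Linkage groups are formed by single-linkage closure over pairs passing both
a LOD and a distance gate, then ordered hierarchically: markers are inserted
into a growing framework only while the log10-likelihood margin of their
best position over the second best exceeds the current tier threshold
(tiers 3, 2, then unconditionally at the most likely position), with local
search (exhaustive permutation of sliding 6-marker windows, plus
remove-and-reinsert polishing) run to a fixed point after every tier.
Sex-specific maps re-estimate interval distances from the female- and
male-informative meioses under the locked sex-average order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .dataio import MISSING, GenotypeStudy, GeneticMapTable

LOG10_2 = np.log10(2.0)
UNINFORMATIVE = -1


# ---------------------------------------------------------------------------
# Kosambi mapping function


def kosambi(theta):
    """Map a recombination fraction to Kosambi cM; theta >= 0.5 maps to inf."""
    theta = np.asarray(theta, dtype=float)
    out = np.full(theta.shape, np.inf)
    ok = theta < 0.5
    out[ok] = 25.0 * np.log((1 + 2 * theta[ok]) / (1 - 2 * theta[ok]))
    return float(out) if out.ndim == 0 else out


def kosambi_inverse(d_cM):
    """Inverse Kosambi: theta = 0.5 * tanh(2 d), d in Morgans."""
    d = np.asarray(d_cM, dtype=float) / 100.0
    theta = 0.5 * np.tanh(2.0 * d)
    return float(theta) if theta.ndim == 0 else theta


# ---------------------------------------------------------------------------
# phased meioses


@dataclass
class PhasedMeioses:
    """Grandparental origin of each transmitted allele, per meiosis x marker.

    ``origins[k, j]`` is 0 if meiosis k transmitted marker j's grandpaternal
    allele, 1 for grandmaternal, -1 if uninformative.  ``meta`` aligns row k
    with (parent, progeny, parent sex, family).
    """

    origins: np.ndarray
    meta: pd.DataFrame
    marker_ids: list[str]

    @property
    def n_meioses(self) -> int:
        return self.origins.shape[0]

    @property
    def n_informative(self) -> np.ndarray:
        """Informative meioses per marker."""
        return (self.origins >= 0).sum(axis=0)

    def total_informative(self) -> int:
        return int((self.origins >= 0).sum())

    def sex_mask(self, sex: str) -> np.ndarray:
        return (self.meta["parent_sex"] == sex).to_numpy()

    def col(self, marker_id: str) -> int:
        return self.marker_ids.index(marker_id)


def _parent_phase(codes: np.ndarray, gm, parent_id: str, sire_id: str, dam_id: str):
    """Per-marker phase of a grandparent-traced parent.

    Returns (phase_known, alt_origin): where the parent is heterozygous and
    exactly one grandparental assignment of its alleles is consistent with
    the grandparent genotypes, ``alt_origin`` is 0 when the alt allele came
    from the grandsire, 1 from the granddam.
    """
    gp = codes[gm.sample_row(parent_id)]
    ggs = codes[gm.sample_row(sire_id)]
    ggd = codes[gm.sample_row(dam_id)]
    het = gp == 1
    # can each grandparent have transmitted ref / alt?  missing -> both
    gs_alt = (ggs == MISSING) | (ggs >= 1)
    gs_ref = (ggs == MISSING) | (ggs <= 1)
    gd_alt = (ggd == MISSING) | (ggd >= 1)
    gd_ref = (ggd == MISSING) | (ggd <= 1)
    ok_alt_gs = gs_alt & gd_ref  # alt grandpaternal, ref grandmaternal
    ok_alt_gd = gd_alt & gs_ref
    phase_known = het & (ok_alt_gs ^ ok_alt_gd)
    alt_origin = np.where(ok_alt_gd, 1, 0).astype(np.int8)
    return phase_known, alt_origin


def phase_meioses(study: GenotypeStudy, resolve_ambiguous: bool = True,
                  strict: bool = False,
                  order_positions: Optional[dict] = None) -> PhasedMeioses:
    """Derive informative meioses from grandparent-traced families.

    A meiosis (parent -> progeny, at one marker) is informative iff the
    parent is heterozygous, the grandparental origin of its two alleles is
    deducible from the grandparent genotypes, and the allele it transmitted
    is deducible from the progeny genotype.

    Two modes serve different estimators.  ``strict`` keeps only testcross
    configurations (the mate homozygous at the marker), where every progeny
    genotype reveals the transmitted allele: informativeness is then a
    marker-level property, so recombinant counting is free of selection
    bias — use this channel for distance estimation and the heterogeneity
    statistics.  The default augmented mode additionally reads
    transmissions off homozygous progeny and resolves the remaining
    double-heterozygous slots by linkage context (two tightly linked
    anchors must agree); it roughly doubles the informative meioses and is
    the channel of choice for grouping and ordering, at the price of a
    small attenuation of long-range recombination estimates.
    """
    gm = study.genotypes
    codes = gm.codes
    ped = study.pedigree.df
    by_id = {r.sample_id: r for r in ped.itertuples()}
    n_markers = len(gm.marker_ids)

    children: dict[str, list[tuple[str, str]]] = {}
    for r in ped.itertuples():
        if r.sire_id:
            children.setdefault(r.sire_id, []).append((r.sample_id, r.dam_id))
        if r.dam_id:
            children.setdefault(r.dam_id, []).append((r.sample_id, r.sire_id))

    rows, meta_rows, amb_rows = [], [], []
    for parent_id in sorted(children):
        kids = children[parent_id]
        pr = by_id.get(parent_id)
        if pr is None or not (pr.sire_id and pr.dam_id):
            continue  # parent not grandparent-traced
        if pr.sire_id not in by_id or pr.dam_id not in by_id:
            continue
        phase_known, alt_origin = _parent_phase(codes, gm, parent_id, pr.sire_id, pr.dam_id)

        # first pass: transmissions per child (phase-independent)
        child_blocks = []
        for child_id, other_id in kids:
            if child_id not in gm._srow:
                continue
            gc = codes[gm.sample_row(child_id)]
            go = codes[gm.sample_row(other_id)] if other_id and other_id in gm._srow \
                else np.full_like(gc, MISSING)
            transmitted = np.full(gc.shape, UNINFORMATIVE, dtype=np.int8)
            if strict:
                mate_hom = (go == 0) | (go == 2)
                t = gc - go // 2
                valid = mate_hom & (gc != MISSING) & ((t == 0) | (t == 1))
                transmitted[valid] = t[valid]
                amb_mask = np.zeros(gc.shape, dtype=bool)
            else:
                # progeny homozygous: both transmitted alleles read directly
                transmitted[gc == 0] = 0
                transmitted[gc == 2] = 1
                # progeny het, mate homozygous: the mate's contribution is
                # forced, the focal parent sent the other allele
                amb = gc == 1
                transmitted[amb & (go == 0)] = 1
                transmitted[amb & (go == 2)] = 0
                amb_mask = (gc == 1) & ((go == 1) | (go == MISSING))
            child_blocks.append((child_id, transmitted, amb_mask))

        if order_positions is not None and not strict:
            gp_row = codes[gm.sample_row(parent_id)]
            phase_known, alt_origin = _vote_parent_phase(
                gm.marker_ids, order_positions, gp_row, phase_known, alt_origin,
                child_blocks)

        for child_id, transmitted, amb_mask in child_blocks:
            origin = np.full(transmitted.shape, UNINFORMATIVE, dtype=np.int8)
            info = phase_known & (transmitted >= 0)
            origin[info] = np.where(
                transmitted[info] == 1, alt_origin[info], 1 - alt_origin[info]
            ).astype(np.int8)
            rows.append(origin)
            amb_rows.append((phase_known & amb_mask, alt_origin))
            meta_rows.append(
                dict(parent_id=parent_id, progeny_id=child_id,
                     parent_sex=pr.sex, family_id=by_id[child_id].family_id)
            )

    if rows:
        origins = np.vstack(rows)
    else:
        origins = np.empty((0, n_markers), dtype=np.int8)
    meta = pd.DataFrame(meta_rows, columns=["parent_id", "progeny_id", "parent_sex", "family_id"])

    if resolve_ambiguous and len(rows):
        if order_positions is not None:
            _resolve_ambiguous_slots_ordered(origins, amb_rows, gm.marker_ids,
                                             order_positions)
        else:
            _resolve_ambiguous_slots(origins, amb_rows)
    return PhasedMeioses(origins, meta, list(gm.marker_ids))


def _vote_parent_phase(marker_ids: Sequence[str], order_positions: dict,
                       parent_genotypes: np.ndarray, phase_known: np.ndarray,
                       alt_origin: np.ndarray, child_blocks,
                       min_votes: int = 3, min_margin: int = 2):
    """Recover parent phase at markers the grandparents leave ambiguous.

    Where the parent is heterozygous but both grandparents are too
    (grandparental origin not deducible locus by locus), the phase can
    still be read off the progeny: each child with a known transmission at
    the marker and a resolved origin at the nearest phase-known neighbour
    votes for the phase that links the two.  A clear majority fixes the
    phase; close votes leave the marker unphased.
    """
    phase_known = phase_known.copy()
    alt_origin = alt_origin.copy()
    lg_cols: dict[str, list[int]] = {}
    for j, m in enumerate(marker_ids):
        if m in order_positions:
            lg_cols.setdefault(order_positions[m][0], []).append(j)
    for lg in lg_cols:
        lg_cols[lg].sort(key=lambda j: order_positions[marker_ids[j]][1])

    targets = np.nonzero((parent_genotypes == 1) & ~phase_known)[0]
    for j in targets:
        m = marker_ids[j]
        if m not in order_positions:
            continue
        lg, pos_j = order_positions[m]
        cols = lg_cols[lg]
        # nearest phase-known heterozygous markers of this parent, by cM
        anchors = sorted(
            (c for c in cols if phase_known[c]),
            key=lambda c: abs(order_positions[marker_ids[c]][1] - pos_j))
        votes = [0, 0]
        for _child_id, transmitted, _amb in child_blocks:
            if transmitted[j] < 0:
                continue
            for a in anchors[:3]:
                if transmitted[a] < 0:
                    continue
                origin_a = alt_origin[a] if transmitted[a] == 1 else 1 - alt_origin[a]
                # phase hypothesis: alt at j sits on the same haplotype the
                # child received at the anchor
                vote = origin_a if transmitted[j] == 1 else 1 - origin_a
                votes[vote] += 1
                break
        total = votes[0] + votes[1]
        if total >= min_votes and abs(votes[0] - votes[1]) >= min_margin:
            phase_known[j] = True
            alt_origin[j] = int(votes[1] > votes[0])
    return phase_known, alt_origin


def _resolve_ambiguous_slots_ordered(origins: np.ndarray, amb_rows,
                                     marker_ids: Sequence[str],
                                     order_positions: dict) -> None:
    """Context resolution with a provisional map order available.

    ``order_positions`` maps marker_id -> (lg, position).  Each ambiguous
    slot looks to its nearest resolved neighbour on each side along the
    order; the slot is resolved only when both sides agree, so an error
    would require a double crossover across the slot.  Markers without a
    map position keep their slots uninformative.
    """
    lg_cols: dict[str, list[int]] = {}
    for j, m in enumerate(marker_ids):
        if m in order_positions:
            lg_cols.setdefault(order_positions[m][0], []).append(j)
    for lg in lg_cols:
        lg_cols[lg].sort(key=lambda j: order_positions[marker_ids[j]][1])
    col_rank = {}
    for lg, cols in lg_cols.items():
        for rank, j in enumerate(cols):
            col_rank[j] = (lg, rank)

    for k, (amb_mask, _alt_origin) in enumerate(amb_rows):
        resolved = origins[k] >= 0
        for j in np.nonzero(amb_mask)[0]:
            if j not in col_rank:
                continue
            lg, rank = col_rank[j]
            cols = lg_cols[lg]
            left = right = None
            for p in range(rank - 1, -1, -1):
                if resolved[cols[p]]:
                    left = origins[k, cols[p]]
                    break
            for p in range(rank + 1, len(cols)):
                if resolved[cols[p]]:
                    right = origins[k, cols[p]]
                    break
            if left is not None and right is not None and left == right:
                origins[k, j] = left


def _resolve_ambiguous_slots(origins: np.ndarray, amb_rows, anchor_lod_min: float = 3.0,
                             anchor_theta_max: float = 0.2) -> None:
    """In-place context resolution of double-heterozygous transmission slots.

    From the directly resolved slots, two-point estimates identify for each
    marker its most tightly linked anchor candidates; an ambiguous slot is
    resolved only when the meiosis's origins at its two best available
    anchors agree, and then takes that origin.  A single discordant anchor
    cannot plant a spurious recombinant; unresolved slots stay
    uninformative.
    """
    N, R = pair_count_matrices(origins)
    theta, Z = lod_score(N, R)
    with np.errstate(invalid="ignore"):
        usable = (np.nan_to_num(Z, nan=-1.0) >= anchor_lod_min) & \
                 (np.nan_to_num(theta, nan=1.0) <= anchor_theta_max)
    np.fill_diagonal(usable, False)
    n_markers = origins.shape[1]
    # anchor preference per marker: ascending theta among usable partners
    anchor_order = []
    for j in range(n_markers):
        cand = np.nonzero(usable[j])[0]
        anchor_order.append(cand[np.argsort(theta[j, cand], kind="stable")])

    for k, (amb_mask, alt_origin) in enumerate(amb_rows):
        resolved = origins[k] >= 0
        for j in np.nonzero(amb_mask)[0]:
            votes = []
            for a in anchor_order[j]:
                if resolved[a]:
                    votes.append(origins[k, a])
                    if len(votes) == 2:
                        break
            if len(votes) == 2 and votes[0] == votes[1]:
                origins[k, j] = votes[0]



# ---------------------------------------------------------------------------
# two-point statistics


def lod_score(N, R):
    """Two-point LOD at the phase-known MLE theta_hat = min(R/N, 0.5)."""
    N = np.asarray(N, dtype=float)
    R = np.asarray(R, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(N > 0, np.minimum(R / np.maximum(N, 1), 0.5), np.nan)
        z = (np.where(R > 0, R * np.log10(np.maximum(theta, 1e-300)), 0.0)
             + np.where(N - R > 0, (N - R) * np.log10(np.maximum(1 - theta, 1e-300)), 0.0)
             + N * LOG10_2)
    z = np.where(N > 0, np.maximum(z, 0.0), np.nan)
    if z.ndim == 0:
        return float(theta), float(z)
    return theta, z


def pair_count_matrices(origins: np.ndarray, row_mask: Optional[np.ndarray] = None):
    """All-pairs co-informative meiosis counts N and recombinant counts R."""
    o = origins if row_mask is None else origins[row_mask]
    informative = (o >= 0)
    X = (informative & (o == 1)).astype(np.float64)
    Y = (informative & (o == 0)).astype(np.float64)
    R = X.T @ Y + Y.T @ X
    M = informative.astype(np.float64)
    N = M.T @ M
    return N, R


@dataclass
class TwoPointResult:
    """Recombination estimate for one marker pair, with sex partition."""

    marker_a: str
    marker_b: str
    n: int
    r: int
    theta_hat: float
    lod: float
    n_m: int = 0
    r_m: int = 0
    n_f: int = 0
    r_f: int = 0

    @property
    def has_data(self) -> bool:
        return self.n > 0


def twopoint(phased: PhasedMeioses, pair: tuple[str, str]) -> TwoPointResult:
    """Two-point estimate for a single marker pair from phased meioses."""
    i, j = phased.col(pair[0]), phased.col(pair[1])
    a, b = phased.origins[:, i], phased.origins[:, j]
    both = (a >= 0) & (b >= 0)
    rec = both & (a != b)
    male = phased.sex_mask("M")
    female = phased.sex_mask("F")
    n, r = int(both.sum()), int(rec.sum())
    if n == 0:
        return TwoPointResult(pair[0], pair[1], 0, 0, np.nan, np.nan)
    theta, z = lod_score(n, r)
    return TwoPointResult(
        pair[0], pair[1], n, r, theta, z,
        n_m=int((both & male).sum()), r_m=int((rec & male).sum()),
        n_f=int((both & female).sum()), r_f=int((rec & female).sum()),
    )


def twopoint_by_family(phased: PhasedMeioses, pair: tuple[str, str],
                       by: str = "parent_id") -> pd.DataFrame:
    """Per-family (or per-parent) co-informative and recombinant counts."""
    i, j = phased.col(pair[0]), phased.col(pair[1])
    a, b = phased.origins[:, i], phased.origins[:, j]
    both = (a >= 0) & (b >= 0)
    rec = both & (a != b)
    out = phased.meta.assign(n=both.astype(int), r=rec.astype(int))
    g = out.groupby(by, sort=True)[["n", "r"]].sum().reset_index()
    return g[g["n"] > 0]


# ---------------------------------------------------------------------------
# grouping


def group_markers(marker_ids: Sequence[str], N: np.ndarray, R: np.ndarray,
                  lod_min: float = 10.0, dist_max_cM: float = 30.0):
    """Partition markers by single-linkage closure over qualifying pairs.

    A pair qualifies when its LOD meets ``lod_min`` and its Kosambi distance
    at theta_hat is at most ``dist_max_cM``.  Components of fewer than three
    markers join the orphan pool.
    """
    theta, Z = lod_score(N, R)
    with np.errstate(invalid="ignore"):
        dist = kosambi(np.nan_to_num(theta, nan=0.5))
        edge = (np.nan_to_num(Z, nan=-1.0) >= lod_min) & (dist <= dist_max_cM)
    np.fill_diagonal(edge, False)
    g = nx.Graph()
    g.add_nodes_from(range(len(marker_ids)))
    g.add_edges_from(zip(*np.nonzero(np.triu(edge))))
    groups, orphans = [], []
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    for comp in comps:
        members = sorted(comp)
        if len(members) >= 3:
            groups.append([marker_ids[i] for i in members])
        else:
            orphans.extend(marker_ids[i] for i in members)
    return groups, sorted(orphans)


# ---------------------------------------------------------------------------
# ordering


THETA_ADJ_CAP = 0.45    # keeps plug-in adjacent distances finite
THETA_IMPLIED_FLOOR = 1e-3  # genotyping-error scale; avoids -inf on co-localised pairs
THETA_ADJ_PRIOR = 0.01      # prior mean for adjacent-pair recombination
THETA_ADJ_PRIOR_WEIGHT = 5.0  # pseudo-meioses behind the prior


class OrderObjective:
    """All-pairs two-point log10-likelihood of a marker order.

    Adjacent intervals take plug-in recombination fractions theta = R/N;
    assuming crossovers in disjoint intervals are independent, Trow's
    product formula composes them into an implied recombination fraction
    for every marker pair (1 - 2 theta_ij = prod_k (1 - 2 theta_k)), and
    the objective scores ALL co-informative pairs against those implied
    fractions:

        LL(order) = sum over informative pairs of
                    R log10(theta_implied) + (N - R) log10(1 - theta_implied).

    Scoring every pair (not only adjacent ones) is what makes the criterion
    robust at moderate informativeness: an order that chains a few lucky
    zero-recombinant pairs still has to explain every cross-pair count, so
    it cannot overfit the adjacency structure.
    """

    def __init__(self, N: np.ndarray, R: np.ndarray):
        self.N = np.asarray(N, dtype=float)
        self.R = np.asarray(R, dtype=float)
        # adjacent-interval plug-in estimates are shrunk toward a small
        # prior: a candidate adjacency with no co-informative meioses is
        # treated as close, not pushed to a half-map distance, so weakly
        # informative markers cannot blow up the implied geometry
        w, t0 = THETA_ADJ_PRIOR_WEIGHT, THETA_ADJ_PRIOR
        self.theta_adj = np.minimum((self.R + w * t0) / (self.N + w), THETA_ADJ_CAP)
        self._triu_cache: dict[int, np.ndarray] = {}

    def _triu(self, m: int) -> np.ndarray:
        if m not in self._triu_cache:
            self._triu_cache[m] = np.triu(np.ones((m, m), dtype=bool), 1)
        return self._triu_cache[m]

    def ll_batch(self, orders: np.ndarray) -> np.ndarray:
        """Log10-likelihoods for a (batch, m) array of candidate orders."""
        orders = np.asarray(orders)
        if orders.ndim == 1:
            orders = orders[None, :]
        B, m = orders.shape
        ta = self.theta_adj[orders[:, :-1], orders[:, 1:]]
        # Trow composition: cumulate -ln(1 - 2 theta) along the order
        lq = -np.log(np.maximum(1.0 - 2.0 * ta, 1e-9))
        x = np.concatenate([np.zeros((B, 1)), np.cumsum(lq, axis=1)], axis=1)
        S = np.abs(x[:, :, None] - x[:, None, :])
        thi = np.clip(0.5 * (1.0 - np.exp(-S)), THETA_IMPLIED_FLOOR, 0.5)
        Ns = self.N[orders[:, :, None], orders[:, None, :]]
        Rs = self.R[orders[:, :, None], orders[:, None, :]]
        terms = Rs * np.log10(thi) + (Ns - Rs) * np.log10(1 - thi)
        terms = np.where(Ns > 0, terms, 0.0)
        tri = self._triu(m)
        return terms[:, tri].sum(axis=1)

    def ll(self, order: Sequence[int]) -> float:
        return float(self.ll_batch(np.asarray(order)[None, :])[0])

    def with_theta(self, theta_adj: np.ndarray) -> "OrderObjective":
        """Same data, different adjacent-distance geometry."""
        out = OrderObjective(self.N, self.R)
        out.theta_adj = theta_adj
        return out


def _fit_interval_lengths(N: np.ndarray, R: np.ndarray, order: Sequence[int],
                          x0: Optional[np.ndarray] = None,
                          max_interval_cM: float = 60.0,
                          fit_error_rate: bool = False) -> np.ndarray:
    """Composite-MLE interval lengths (cM) for a fixed order.

    Each interval's recombination fraction is inverse-Kosambi of its
    length; fractions compose across intervals by Trow's product formula
    (independent crossovers), and every co-informative pair contributes its
    binomial log-likelihood at the composed fraction.  With
    ``fit_error_rate`` a shared false-recombinant nuisance rate eps is
    co-estimated (observed theta = eps + (1 - 2 eps) theta_implied), so
    genotyping artifacts do not inflate every interval.
    """
    from scipy.optimize import minimize

    o = np.asarray(order)
    m = len(o)
    Ns = N[np.ix_(o, o)]
    Rs = R[np.ix_(o, o)]
    iu, ju = np.triu_indices(m, 1)
    keep = Ns[iu, ju] > 0
    iu, ju = iu[keep], ju[keep]
    n, r = Ns[iu, ju], Rs[iu, ju]
    if x0 is None:
        x0 = np.ones(m - 1)
    x0 = np.clip(np.nan_to_num(np.asarray(x0, dtype=float), nan=1.0),
                 1e-3, max_interval_cM)
    span = np.zeros((len(iu), m - 1))
    for p, (i, j) in enumerate(zip(iu, ju)):
        span[p, i:j] = 1.0
    ln10 = np.log(10.0)
    n_d = m - 1

    def negll_grad(params):
        d = params[:n_d]
        eps = params[n_d] if fit_error_rate else 0.0
        t = np.tanh(2.0 * d / 100.0)          # 2 * theta_k
        lq = np.log(np.maximum(1.0 - t, 1e-12))
        S = span @ lq
        thi = 0.5 * (1.0 - np.exp(S))
        th = np.clip(eps + (1.0 - 2.0 * eps) * thi, 1e-9, 0.5 - 1e-9)
        ll = (r * np.log(th) + (n - r) * np.log(1 - th)) / ln10
        w = (r / th - (n - r) / (1 - th)) / ln10
        # d th / d lq_k = (1 - 2 eps) * (-0.5 exp(S)); d lq_k / d d_k = -(1 + t_k)/50
        dll_dS = w * (1.0 - 2.0 * eps) * (-0.5 * np.exp(S))
        grad_d = (span.T @ dll_dS) * (-(1.0 + t) / 50.0)
        if fit_error_rate:
            grad_eps = float((w * (1.0 - 2.0 * thi)).sum())
            return -ll.sum(), -np.concatenate([grad_d, [grad_eps]])
        return -ll.sum(), -grad_d

    bounds = [(0.0, max_interval_cM)] * n_d
    start = x0
    if fit_error_rate:
        bounds.append((0.0, 0.05))
        start = np.concatenate([x0, [0.005]])
    res = minimize(negll_grad, start, jac=True, method="L-BFGS-B",
                   bounds=bounds, options=dict(maxiter=500))
    return res.x[:n_d]


def order_log10_likelihood(order: Sequence[int], N: np.ndarray, R: np.ndarray) -> float:
    """All-pairs order log10-likelihood (see :class:`OrderObjective`)."""
    if len(order) < 2:
        return 0.0
    return OrderObjective(N, R).ll(order)


def _insertion_orders(order: list[int], x: int) -> np.ndarray:
    """All orders obtained by inserting x into each gap of ``order``."""
    m = len(order)
    out = np.empty((m + 1, m + 1), dtype=int)
    base = np.asarray(order)
    for p in range(m + 1):
        out[p, :p] = base[:p]
        out[p, p] = x
        out[p, p + 1:] = base[p:]
    return out


def _flips_window(order: list[int], obj: OrderObjective, w: int = 6) -> bool:
    """One sweep of exhaustive permutation of every sliding window; True if improved."""
    improved = False
    m = len(order)
    if m < 3:
        return False
    w = min(w, m)
    perms = list(permutations(range(w)))
    for s in range(m - w + 1):
        window = order[s:s + w]
        cands = np.tile(np.asarray(order), (len(perms), 1))
        for k, perm in enumerate(perms):
            cands[k, s:s + w] = [window[p] for p in perm]
        lls = obj.ll_batch(cands)
        best = int(np.argmax(lls))
        if lls[best] > lls[0] + 1e-9 and list(perms[best]) != list(range(w)):
            order[s:s + w] = [window[p] for p in perms[best]]
            improved = True
    return improved


def _polish(order: list[int], obj: OrderObjective) -> bool:
    """Remove-and-reinsert every marker at its best position; True if improved."""
    improved = False
    for x in list(order):
        pos = order.index(x)
        rest = order[:pos] + order[pos + 1:]
        if len(rest) < 2:
            continue
        cands = _insertion_orders(rest, x)
        lls = obj.ll_batch(cands)
        best_p = int(np.argmax(lls))
        if lls[best_p] > obj.ll(order) + 1e-9:
            order[:] = list(cands[best_p])
            improved = True
    return improved


def _local_search(order: list[int], obj: OrderObjective, max_sweeps: int = 20) -> None:
    for _ in range(max_sweeps):
        moved = _flips_window(order, obj)
        moved |= _polish(order, obj)
        if not moved:
            break


@dataclass
class LinkageGroup:
    """An ordered linkage group with adjacent-interval estimates."""

    name: str
    marker_ids: list[str]
    thetas: np.ndarray          # adjacent theta_hat, len m-1
    intervals_cM: np.ndarray    # Kosambi distances, len m-1
    tiers: dict[str, str]       # marker -> {"lod3", "lod2", "best"}
    log10_likelihood: float
    colocalised: list[str] = field(default_factory=list)
    intervals_f: Optional[np.ndarray] = None
    intervals_m: Optional[np.ndarray] = None

    @property
    def length_cM(self) -> float:
        return float(np.nansum(self.intervals_cM))

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def positions(self) -> np.ndarray:
        """Cumulative sex-average positions; undefined intervals count 0 cM."""
        return np.concatenate([[0.0], np.cumsum(np.nan_to_num(self.intervals_cM))])


def _adjacent_stats(order_ids: list[str], phased: PhasedMeioses,
                    row_mask: Optional[np.ndarray] = None):
    """(theta, cM, N, R) per adjacent interval of an ordered marker list."""
    cols = [phased.col(m) for m in order_ids]
    o = phased.origins if row_mask is None else phased.origins[row_mask]
    thetas, dists, Ns, Rs = [], [], [], []
    for a, b in zip(cols[:-1], cols[1:]):
        va, vb = o[:, a], o[:, b]
        both = (va >= 0) & (vb >= 0)
        n = int(both.sum())
        r = int((both & (va != vb)).sum())
        Ns.append(n)
        Rs.append(r)
        if n == 0:
            thetas.append(np.nan)
            dists.append(np.nan)
        else:
            t = min(r / n, 0.5)
            thetas.append(t)
            # cap: a free pair estimate of 0.5 would map to infinity
            dists.append(kosambi(min(t, 0.49)))
    return (np.array(thetas), np.array(dists), np.array(Ns), np.array(Rs))


def _tiered_insertion(obj: OrderObjective, seed_pair: tuple[int, int],
                      unplaced_seq: Sequence[int], tiers: Sequence[float]):
    """One pass of margin-gated incremental insertion plus local search."""
    order = [int(seed_pair[0]), int(seed_pair[1])]
    tier_names = {3.0: "lod3", 2.0: "lod2", 0.0: "best"}
    placed_tier: dict[int, str] = {}
    colocalised: list[int] = []
    unplaced = list(unplaced_seq)
    for tier in tiers:
        tname = tier_names.get(tier, f"margin{tier:g}")
        progress = True
        while progress and unplaced:
            progress = False
            for x in list(unplaced):
                lls = obj.ll_batch(_insertion_orders(order, x))
                srt = np.sort(lls)[::-1]
                margin = srt[0] - srt[1] if len(srt) > 1 else np.inf
                if margin >= tier - 1e-12:
                    if margin <= 1e-12 and tier == 0.0:
                        # dead tie at the loosest tier: lower coordinate wins
                        colocalised.append(x)
                    order.insert(int(np.argmax(lls)), x)
                    placed_tier[x] = tname
                    unplaced.remove(x)
                    progress = True
        _local_search(order, obj)
    return order, placed_tier, colocalised


def _fitted_theta_matrix(N: np.ndarray, R: np.ndarray, order: list[int],
                         x0: np.ndarray) -> np.ndarray:
    """Pairwise theta implied by composite-MLE interval lengths under ``order``."""
    d = _fit_interval_lengths(N, R, order, x0=x0)
    lq = -np.log(np.maximum(1.0 - np.tanh(2.0 * d / 100.0), 1e-12))
    x = np.concatenate([[0.0], np.cumsum(lq)])
    pos = np.empty(len(order))
    pos[np.asarray(order)] = x
    S = np.abs(pos[:, None] - pos[None, :])
    return np.minimum(0.5 * (1.0 - np.exp(-S)), THETA_ADJ_CAP)


def build_framework(group: Sequence[str], phased: PhasedMeioses,
                    tiers: Sequence[float] = (3.0, 2.0, 0.0),
                    name: str = "LG", n_starts: int = 3,
                    n_refine: int = 3) -> LinkageGroup:
    """Order one candidate group by hierarchical tiered insertion.

    Seeds with the highest-LOD pair, inserts markers while the best-position
    margin meets the tier, and runs flips-6 + polish to a fixed point after
    each tier; the final tier (margin 0) places every remaining marker at
    its most likely position, with exact ties going to the lower coordinate
    and recorded as co-localised.  The insertion sequence is restarted
    ``n_starts`` times (informativeness order, then seeded shuffles) keeping
    the best final likelihood, and the winning order is refined by
    coordinate ascent: interval lengths are refitted by composite MLE, the
    objective geometry rebuilt from the fitted positions, and the local
    search repeated until the order is stable.
    """
    ids = list(group)
    if len(ids) < 3:
        raise ValueError("framework ordering needs at least three markers")
    cols = np.array([phased.col(m) for m in ids])
    N, R = pair_count_matrices(phased.origins[:, cols])
    obj = OrderObjective(N, R)
    theta, Z = lod_score(N, R)
    Zi = np.nan_to_num(Z, nan=-np.inf)
    np.fill_diagonal(Zi, -np.inf)
    a, b = np.unravel_index(np.argmax(Zi), Zi.shape)

    base = [k for k in range(len(ids)) if k not in (int(a), int(b))]
    base.sort(key=lambda k: -N[k, :].sum())
    rng = np.random.default_rng(0)
    starts = [list(base)] + [list(rng.permutation(base)) for _ in range(n_starts - 1)]

    best = None
    for seq in starts:
        order, ptier, coloc = _tiered_insertion(obj, (int(a), int(b)), seq, tiers)
        ll = obj.ll(order)
        if best is None or ll > best[0]:
            best = (ll, order, ptier, coloc)
    _, order, placed_tier, coloc_idx = best

    # coordinate ascent between interval lengths and order
    cur_obj = obj
    for _ in range(n_refine):
        x0 = np.array([kosambi(min(float(cur_obj.theta_adj[i, j]), 0.45))
                       for i, j in zip(order[:-1], order[1:])])
        cur_obj = obj.with_theta(_fitted_theta_matrix(N, R, order, x0))
        prev = list(order)
        _local_search(order, cur_obj)
        if order == prev:
            break

    for m_idx in (int(a), int(b)):
        placed_tier[m_idx] = "lod3"

    # canonical orientation: reversal leaves the likelihood unchanged
    ordered_ids = [ids[k] for k in order]
    if ordered_ids[0] > ordered_ids[-1]:
        ordered_ids.reverse()
    thetas, dists, _, _ = _adjacent_stats(ordered_ids, phased)
    ll = cur_obj.ll([ids.index(m) for m in ordered_ids])
    return LinkageGroup(name, ordered_ids, thetas, dists,
                        {ids[k]: placed_tier.get(k, "lod3") for k in range(len(ids))},
                        ll, [ids[k] for k in coloc_idx])


# ---------------------------------------------------------------------------
# whole-map assembly


@dataclass
class GeneticMap:
    """A built map: ordered linkage groups plus the residual orphan pool."""

    groups: list[LinkageGroup]
    orphans: list[str]

    @property
    def total_length_cM(self) -> float:
        return float(sum(g.length_cM for g in self.groups))

    def mapped_markers(self) -> list[str]:
        return [m for g in self.groups for m in g.marker_ids]

    def group_of(self, marker_id: str) -> Optional[str]:
        for g in self.groups:
            if marker_id in g.marker_ids:
                return g.name
        return None

    def to_table(self, lode_placements: Optional[dict[str, str]] = None) -> GeneticMapTable:
        lode_placements = lode_placements or {}
        rows = []
        for g in self.groups:
            pos = g.positions()
            pos_f = (np.concatenate([[0.0], np.cumsum(np.nan_to_num(g.intervals_f))])
                     if g.intervals_f is not None else np.full(len(pos), np.nan))
            pos_m = (np.concatenate([[0.0], np.cumsum(np.nan_to_num(g.intervals_m))])
                     if g.intervals_m is not None else np.full(len(pos), np.nan))
            for k, m in enumerate(g.marker_ids):
                rows.append(dict(marker_id=m, lg=g.name, pos_sexavg=float(pos[k]),
                                 pos_f=float(pos_f[k]), pos_m=float(pos_m[k]),
                                 method=lode_placements.get(m, "linkage")))
        for m in self.orphans:
            rows.append(dict(marker_id=m, lg="unplaced", pos_sexavg=0.0,
                             pos_f=np.nan, pos_m=np.nan, method="orphan"))
        return GeneticMapTable(pd.DataFrame(rows, columns=["marker_id", "lg", "pos_sexavg",
                                                           "pos_f", "pos_m", "method"]))


def build_map(phased: PhasedMeioses, lod_min: float = 10.0, dist_max_cM: float = 30.0,
              tiers: Sequence[float] = (3.0, 2.0, 0.0),
              min_informative: int = 1, n_starts: int = 3,
              n_refine: int = 3) -> GeneticMap:
    """Group and order all markers with enough informative meioses."""
    n_info = phased.n_informative
    usable = [m for m, n in zip(phased.marker_ids, n_info) if n >= min_informative]
    cols = np.array([phased.col(m) for m in usable])
    N, R = pair_count_matrices(phased.origins[:, cols])
    groups, orphans = group_markers(usable, N, R, lod_min, dist_max_cM)
    built = [build_framework(g, phased, tiers, name=f"LG{i + 1}",
                             n_starts=n_starts, n_refine=n_refine)
             for i, g in enumerate(sorted(groups, key=len, reverse=True))]
    orphans += [m for m in phased.marker_ids if m not in usable]
    return GeneticMap(built, sorted(set(orphans)))


def prune_double_recombinants(phased: PhasedMeioses, gmap: GeneticMap,
                              max_cM: float = 10.0) -> PhasedMeioses:
    """Mask isolated origin flips along the built order.

    A single-marker origin that disagrees with BOTH flanking informative
    origins of the same meiosis implies a double crossover within a short
    window; within ``max_cM`` such events are overwhelmingly genotyping or
    phasing artifacts and the slot is set uninformative.  Interval
    distances should be recomputed afterwards.
    """
    origins = phased.origins.copy()
    for g in gmap.groups:
        cols = np.array([phased.col(m) for m in g.marker_ids])
        pos = g.positions()
        block = origins[:, cols]
        for k in range(block.shape[0]):
            row = block[k]
            inf = np.nonzero(row >= 0)[0]
            if len(inf) < 3:
                continue
            vals = row[inf]
            mid = (vals[1:-1] != vals[:-2]) & (vals[1:-1] != vals[2:])
            span = pos[inf[2:]] - pos[inf[:-2]]
            kill = inf[1:-1][mid & (span <= max_cM)]
            if len(kill):
                row[kill] = UNINFORMATIVE
        origins[:, cols] = block
    return PhasedMeioses(origins, phased.meta, phased.marker_ids)


def recalculate_intervals(gmap: GeneticMap, phased: PhasedMeioses) -> GeneticMap:
    """Refresh every group's adjacent theta and Kosambi intervals."""
    for g in gmap.groups:
        thetas, dists, _, _ = _adjacent_stats(g.marker_ids, phased)
        g.thetas, g.intervals_cM = thetas, dists
    return gmap


def fit_intervals(gmap: GeneticMap, phased: PhasedMeioses,
                  max_interval_cM: float = 60.0,
                  fit_error_rate: bool = True) -> GeneticMap:
    """Composite-MLE interval distances from ALL informative pairs.

    With the order locked, the interval lengths d_k are fitted to maximise
    the sum over every co-informative marker pair of its two-point
    log-likelihood at the recombination fraction implied by composing the
    intervening inverse-Kosambi fractions with Trow's product formula.
    Long- and mid-range pairs anchor the geometry, so the estimate is
    robust both to locally unresolved orders (which would inflate plug-in
    adjacent estimates) and to zero-recombinant adjacent pairs (which
    would deflate them).  Adjacent plug-in theta_hat values are kept for
    reporting.
    """
    for g in gmap.groups:
        if g.n_markers < 2:
            continue
        cols = np.array([phased.col(mk) for mk in g.marker_ids])
        N, R = pair_count_matrices(phased.origins[:, cols])
        g.intervals_cM = _fit_interval_lengths(
            N, R, list(range(g.n_markers)), x0=g.intervals_cM,
            max_interval_cM=max_interval_cM, fit_error_rate=fit_error_rate)
    return gmap


def sex_specific_maps(gmap: GeneticMap, phased: PhasedMeioses,
                      fit: bool = False) -> GeneticMap:
    """Recalculate interval distances per sex under the locked sex-average order.

    Intervals with zero informative meioses in a sex are reported as NaN,
    never imputed; per-sex totals are over defined intervals only.  With
    ``fit`` the per-sex intervals come from the all-pairs composite MLE
    restricted to that sex's meioses (lower variance than adjacent plug-in
    counting); undefined intervals stay NaN.
    """
    male = phased.sex_mask("M")
    female = phased.sex_mask("F")
    for g in gmap.groups:
        _, dist_f, n_f, _ = _adjacent_stats(g.marker_ids, phased, female)
        _, dist_m, n_m, _ = _adjacent_stats(g.marker_ids, phased, male)
        if fit and g.n_markers >= 3:
            cols = np.array([phased.col(m) for m in g.marker_ids])
            for mask, plug, n_adj, attr in ((female, dist_f, n_f, "intervals_f"),
                                            (male, dist_m, n_m, "intervals_m")):
                N, R = pair_count_matrices(phased.origins[:, cols], mask)
                fitted = _fit_interval_lengths(N, R, list(range(g.n_markers)),
                                               x0=plug, fit_error_rate=True)
                fitted = np.where(np.asarray(n_adj) == 0, np.nan, fitted)
                setattr(g, attr, fitted)
        else:
            g.intervals_f = dist_f
            g.intervals_m = dist_m
    return gmap


def insert_orphans(gmap: GeneticMap, phased: PhasedMeioses,
                   lod_min: float = 3.0) -> tuple[GeneticMap, list[str]]:
    """Two-point insertion of orphans into built groups.

    An orphan joins the group holding its best two-point LOD when that LOD
    meets ``lod_min`` and no second group ties it; insertion position is the
    most likely gap under the adjacent-interval likelihood.
    """
    placed: list[str] = []
    for orphan in list(gmap.orphans):
        oc = phased.col(orphan)
        best: list[tuple[float, LinkageGroup]] = []
        for g in gmap.groups:
            cols = np.array([phased.col(m) for m in g.marker_ids])
            vo = phased.origins[:, oc]
            om = phased.origins[:, cols]
            both = (vo[:, None] >= 0) & (om >= 0)
            n = both.sum(axis=0).astype(float)
            r = (both & (vo[:, None] != om)).sum(axis=0).astype(float)
            _, z = lod_score(n, r)
            zmax = np.nanmax(z) if np.isfinite(np.nanmax(z, initial=-np.inf)) else -np.inf
            best.append((float(zmax), g))
        best.sort(key=lambda t: -t[0])
        if not best or not np.isfinite(best[0][0]) or best[0][0] < lod_min:
            continue
        if len(best) > 1 and abs(best[0][0] - best[1][0]) < 1e-9:
            continue  # ambiguous between two groups
        g = best[0][1]
        ids = list(g.marker_ids) + [orphan]
        cols = np.array([phased.col(m) for m in ids])
        N, R = pair_count_matrices(phased.origins[:, cols])
        obj = OrderObjective(N, R)
        order = list(range(len(g.marker_ids)))
        lls = obj.ll_batch(_insertion_orders(order, len(ids) - 1))
        p = int(np.argmax(lls))
        g.marker_ids.insert(p, orphan)
        g.tiers[orphan] = "best"
        thetas, dists, _, _ = _adjacent_stats(g.marker_ids, phased)
        g.thetas, g.intervals_cM = thetas, dists
        placed.append(orphan)
        gmap.orphans.remove(orphan)
    return gmap, placed


def fit_sex_expansion(gmap: GeneticMap, phased: PhasedMeioses) -> tuple[float, float, float]:
    """Genome-wide per-sex map scale under the locked order.

    Holding the sex-average interval profile fixed, each sex's meioses fit
    a single multiplicative scale a (intervals a * d_k) by composite MLE
    over all of that sex's co-informative pairs.  Returns
    (scale_female, scale_male, female:male ratio).  Pooling every pair into
    one parameter gives a far steadier genome ratio than dividing two sums
    of per-interval estimates.
    """
    from scipy.optimize import minimize_scalar

    def negll_for(mask) -> float:
        def negll(a: float) -> float:
            total = 0.0
            for g in gmap.groups:
                if g.n_markers < 2:
                    continue
                cols = np.array([phased.col(m) for m in g.marker_ids])
                N, R = pair_count_matrices(phased.origins[:, cols], mask)
                m = g.n_markers
                d = np.nan_to_num(g.intervals_cM, nan=0.0) * a
                lq = np.log(np.maximum(1.0 - np.tanh(2.0 * d / 100.0), 1e-12))
                x = np.concatenate([[0.0], np.cumsum(lq)])
                S = np.abs(x[:, None] - x[None, :])
                th = np.clip(0.5 * (1.0 - np.exp(-S)), 1e-9, 0.5 - 1e-9)
                iu, ju = np.triu_indices(m, 1)
                keep = N[iu, ju] > 0
                n, r = N[iu, ju][keep], R[iu, ju][keep]
                t = th[iu, ju][keep]
                total -= float((r * np.log(t) + (n - r) * np.log(1 - t)).sum())
            return total
        res = minimize_scalar(negll, bounds=(0.2, 3.0), method="bounded",
                              options=dict(xatol=1e-4))
        return float(res.x)

    a_f = negll_for(phased.sex_mask("F"))
    a_m = negll_for(phased.sex_mask("M"))
    return a_f, a_m, a_f / a_m


def map_study(study: GenotypeStudy, lod_min: float = 10.0, dist_max_cM: float = 30.0,
              tiers: Sequence[float] = (3.0, 2.0, 0.0), orphan_lod: float = 3.0,
              mask_errors: bool = True):
    """Full mapping pipeline on one study.

    Mendelian-inconsistent progeny cells are masked, the augmented phasing
    channel drives grouping/ordering/orphan insertion, and the strict
    (testcross-only, selection-free) channel re-estimates all interval
    distances and the sex-specific maps under the locked order.

    Returns (map, augmented phasing, strict phasing).
    """
    from .qc import mask_mendelian_errors

    if mask_errors:
        study = mask_mendelian_errors(study)
    phased = phase_meioses(study)
    phased_strict = phase_meioses(study, strict=True)
    # round 1: provisional order from the anchor-resolved phasing (cheap)
    gmap = build_map(phased, lod_min=lod_min, dist_max_cM=dist_max_cM, tiers=tiers,
                     n_starts=1, n_refine=1)
    # round 2: re-phase with flanking context along the provisional order
    # (both-side agreement removes nearly all imputation errors), rebuild
    positions = {}
    for g in gmap.groups:
        for m, p in zip(g.marker_ids, g.positions()):
            positions[m] = (g.name, float(p))
    phased = phase_meioses(study, order_positions=positions)
    gmap = build_map(phased, lod_min=lod_min, dist_max_cM=dist_max_cM, tiers=tiers)
    gmap, _ = insert_orphans(gmap, phased, lod_min=orphan_lod)
    gmap = recalculate_intervals(gmap, phased_strict)  # plug-in thetas for reporting
    gmap = fit_intervals(gmap, phased_strict)          # composite-MLE distances
    gmap = sex_specific_maps(gmap, phased_strict)
    return gmap, phased, phased_strict


def merge_candidates(gmap: GeneticMap, phased: PhasedMeioses, k_distal: int = 5,
                     lod_min: float = 3.0) -> pd.DataFrame:
    """Two-point screen of distal markers for linkage-group merges.

    For every ordered group pair and end orientation, reports the maximum
    two-point LOD among the k x k distal marker pairs when it meets
    ``lod_min``.
    """
    rows = []
    groups = gmap.groups
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            gi, gj = groups[i], groups[j]
            ends_i = {"head": gi.marker_ids[:k_distal], "tail": gi.marker_ids[-k_distal:]}
            ends_j = {"head": gj.marker_ids[:k_distal], "tail": gj.marker_ids[-k_distal:]}
            for ei, mi in ends_i.items():
                for ej, mj in ends_j.items():
                    zbest, pair_best = -np.inf, None
                    for ma in mi:
                        for mb in mj:
                            tp = twopoint(phased, (ma, mb))
                            if tp.has_data and tp.lod > zbest:
                                zbest, pair_best = tp.lod, (ma, mb)
                    if pair_best is not None and zbest >= lod_min:
                        rows.append(dict(lg_a=gi.name, end_a=ei, lg_b=gj.name, end_b=ej,
                                         marker_a=pair_best[0], marker_b=pair_best[1],
                                         lod=zbest))
    return pd.DataFrame(rows, columns=["lg_a", "end_a", "lg_b", "end_b",
                                       "marker_a", "marker_b", "lod"])
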