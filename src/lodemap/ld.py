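"""Pairwise linkage disequilibrium and LODE placement of orphan markers.

Two-locus haplotype frequencies are estimated from unphased diploid
genotypes by the standard EM algorithm (double heterozygotes are the only
ambiguous class), from which D, |D'| and r-squared follow.  The EM is
vectorised over marker pairs so whole-map decay profiles and orphan-vs-map
scans stay cheap.

LODE (locus ordering by disequilibrium) places an orphan marker in two
steps: first assign it to the linkage group holding at least ``min_pairs``
mapped partners with r-squared >= ``r2_min`` (the candidate group must
strictly beat every other on qualifying-pair count, then on maximum
r-squared, else the orphan stays unassigned); second, estimate its position
as the r-squared-weighted mean cM of its qualifying partners (the
maximum-r-squared partner position is reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dataio import MISSING, GenotypeStudy, GeneticMapTable

EM_TOL = 1e-10
EM_MAX_ITER = 1000


# ---------------------------------------------------------------------------
# two-locus EM, vectorised over pairs


def _pair_genotype_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 joint genotype counts (flattened, row = locus A) over non-missing pairs."""
    ok = (g1 != MISSING) & (g2 != MISSING)
    idx = g1[ok] * 3 + g2[ok]
    return np.bincount(idx, minlength=9).astype(float)


def em_haplotype_freqs_batch(counts9: np.ndarray):
    """EM haplotype frequencies for many pairs at once.

    ``counts9`` is (n_pairs, 9), joint genotype counts with locus-A genotype
    as the row index (alt-allele dose), locus-B as column.  Returns
    (freqs (n_pairs, 4) ordered [AB, Ab, aB, ab] with "A"/"B" the REF
    alleles, n (n_pairs,), converged flags).  The per-iteration expected
    complete-data log-likelihood is non-decreasing; a safety assertion
    guards each step.
    """
    c = np.asarray(counts9, dtype=float)
    n = c.sum(axis=1)
    npairs = c.shape[0]
    # known gamete contributions: genotype (i, j) contributes known counts to
    # haplotypes except the double-het cell (1,1), split by phase each round
    # haplotype order: 0=AB (ref,ref), 1=Ab, 2=aB, 3=ab  (a, b = alt alleles)
    known = np.zeros((npairs, 4))
    # i, j are alt-allele doses at A and B; with at most one het locus the
    # two gametes of an individual are phase-determined
    for i in range(3):
        for j in range(3):
            if i == 1 and j == 1:
                continue
            cell = c[:, 3 * i + j]
            if i == 1:            # A het, B hom
                gametes = [(1, j // 2), (0, j // 2)]
            elif j == 1:          # B het, A hom
                gametes = [(i // 2, 1), (i // 2, 0)]
            else:                 # both hom
                gametes = [(i // 2, j // 2)] * 2
            for xa, xb in gametes:
                known[:, 2 * xa + xb] += cell
    dh = c[:, 4]  # double heterozygotes: AaBb

    freqs = np.full((npairs, 4), 0.25)
    total_gametes = 2.0 * n
    ok = total_gametes > 0
    prev_ll = np.full(npairs, -np.inf)
    converged = np.zeros(npairs, dtype=bool)
    for _ in range(EM_MAX_ITER):
        p = freqs
        # P(phase AB/ab) vs (Ab/aB) for double hets
        num = p[:, 0] * p[:, 3]
        den = num + p[:, 1] * p[:, 2]
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
        new = known.copy()
        new[:, 0] += dh * w
        new[:, 3] += dh * w
        new[:, 1] += dh * (1 - w)
        new[:, 2] += dh * (1 - w)
        with np.errstate(invalid="ignore", divide="ignore"):
            new = np.where(ok[:, None], new / np.where(ok, total_gametes, 1.0)[:, None], 0.25)
        # observed-data log-likelihood (up to a constant): known haps + dh mix
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = (known * np.log(np.where(new > 0, new, 1.0))).sum(axis=1)
            mix = new[:, 0] * new[:, 3] + new[:, 1] * new[:, 2]
            ll += dh * np.log(np.where(mix > 0, mix, 1.0))
        assert np.all(ll[ok] >= prev_ll[ok] - 1e-8), "EM log-likelihood decreased"
        delta = np.abs(new - freqs).max(axis=1)
        freqs = new
        newly = delta < EM_TOL
        converged |= newly
        prev_ll = ll
        if np.all(converged | ~ok):
            break
    return freqs, n, converged


def em_haplotype_freqs(g1: np.ndarray, g2: np.ndarray):
    """Haplotype frequencies [AB, Ab, aB, ab] for one genotype-column pair."""
    counts = _pair_genotype_counts(np.asarray(g1, dtype=np.int8),
                                   np.asarray(g2, dtype=np.int8))
    freqs, n, conv = em_haplotype_freqs_batch(counts[None, :])
    return freqs[0], int(n[0]), bool(conv[0])


# ---------------------------------------------------------------------------
# LD statistics


@dataclass
class LDPair:
    marker_a: str
    marker_b: str
    freqs: tuple          # (pAB, pAb, paB, pab)
    d: float
    d_prime: float        # |D'|
    r2: float
    n_samples: int
    map_distance_cM: float = float("nan")
    defined: bool = True


def ld_pair_stats(freqs) -> tuple[float, float, float, bool]:
    """(D, |D'|, r2, defined) from 4 haplotype frequencies [AB, Ab, aB, ab]."""
    pAB, pAb, paB, pab = (float(x) for x in freqs)
    pA = pAB + pAb
    pB = pAB + paB
    pa, pb = 1 - pA, 1 - pB
    denom = pA * pa * pB * pb
    if denom <= 0:
        return float("nan"), float("nan"), float("nan"), False
    d = pAB - pA * pB
    dmax = min(pA * pb, pa * pB) if d > 0 else min(pA * pB, pa * pb)
    d_prime = abs(d) / dmax if dmax > 0 else float("nan")
    r2 = d * d / denom
    return d, d_prime, r2, True


def ld_pairs(study: GenotypeStudy, pairs: Sequence[tuple[str, str]],
             sample_ids: Optional[Sequence[str]] = None) -> list[LDPair]:
    """EM-based LD statistics for an explicit list of marker pairs."""
    gm = study.genotypes
    rows = (np.array([gm.sample_row(s) for s in sample_ids])
            if sample_ids is not None else np.arange(len(gm.sample_ids)))
    counts = np.vstack([
        _pair_genotype_counts(gm.codes[rows, gm.marker_col(a)],
                              gm.codes[rows, gm.marker_col(b)])
        for a, b in pairs
    ])
    freqs, n, _ = em_haplotype_freqs_batch(counts)
    out = []
    for k, (a, b) in enumerate(pairs):
        d, dp, r2, defined = ld_pair_stats(freqs[k])
        out.append(LDPair(a, b, tuple(freqs[k]), d, dp, r2, int(n[k]),
                          defined=defined))
    return out


def ld_sample(study: GenotypeStudy, mode: str = "parents") -> list[str]:
    """Samples entering LD estimation.

    ``parents`` (default) uses the non-progeny generations — full-sib
    progeny inflate LD; ``all`` uses every sample.
    """
    ped = study.pedigree.df
    if mode == "all":
        return list(ped["sample_id"])
    if mode == "parents":
        return list(ped.loc[ped["generation"] != "progeny", "sample_id"])
    raise ValueError(f"unknown LD sample mode: {mode}")


def ld_decay_profile(study: GenotypeStudy, gmap: GeneticMapTable,
                     bin_edges: Sequence[float],
                     sample_mode: str = "parents") -> pd.DataFrame:
    """Within-group pairwise LD binned by map distance.

    Returns one row per bin with pair counts and mean/median r2 and |D'|;
    the adjacent-pair summary is appended as an extra row (bin label
    ``adjacent``).  Empty bins are reported with count 0.
    """
    samples = ld_sample(study, sample_mode)
    mapped = gmap.df[gmap.df["method"] != "orphan"]
    pairs, dists, adjacent = [], [], []
    for lg, sub in mapped.groupby("lg", sort=False):
        ids = sub["marker_id"].tolist()
        pos = sub["pos_sexavg"].to_numpy()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pairs.append((ids[i], ids[j]))
                dists.append(abs(pos[j] - pos[i]))
                adjacent.append(j == i + 1)
    if not pairs:
        return pd.DataFrame(columns=["bin", "lo", "hi", "n_pairs",
                                     "mean_r2", "median_r2", "mean_dprime"])
    stats = ld_pairs(study, pairs, samples)
    df = pd.DataFrame(dict(
        dist=dists, adjacent=adjacent,
        r2=[s.r2 for s in stats], dprime=[s.d_prime for s in stats],
        defined=[s.defined for s in stats],
    ))
    df = df[df["defined"]]
    rows = []
    edges = list(bin_edges)
    for lo, hi in zip(edges[:-1], edges[1:]):
        sub = df[(df["dist"] >= lo) & (df["dist"] < hi)]
        rows.append(dict(bin=f"[{lo:g},{hi:g})", lo=lo, hi=hi, n_pairs=len(sub),
                         mean_r2=sub["r2"].mean() if len(sub) else float("nan"),
                         median_r2=sub["r2"].median() if len(sub) else float("nan"),
                         mean_dprime=sub["dprime"].mean() if len(sub) else float("nan")))
    adj = df[df["adjacent"]]
    rows.append(dict(bin="adjacent", lo=float("nan"), hi=float("nan"),
                     n_pairs=len(adj),
                     mean_r2=adj["r2"].mean() if len(adj) else float("nan"),
                     median_r2=adj["r2"].median() if len(adj) else float("nan"),
                     mean_dprime=adj["dprime"].mean() if len(adj) else float("nan")))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LODE


@dataclass
class LODEPlacement:
    marker_id: str
    lg: Optional[str]
    n_qualifying_pairs: int
    max_r2: float
    position_cM: float = float("nan")
    max_r2_partner_position_cM: float = float("nan")
    support: list = field(default_factory=list)  # (partner, r2, pos)
    reason: str = ""

    @property
    def assigned(self) -> bool:
        return self.lg is not None


def lode_assign_lg(orphan: str, study: GenotypeStudy, gmap: GeneticMapTable,
                   r2_min: float = 0.1, min_pairs: int = 3,
                   sample_mode: str = "parents") -> LODEPlacement:
    """Assignment step: pick the group with the most qualifying LD partners.

    Requires ``min_pairs`` partners at r2 >= ``r2_min`` on a single group
    that strictly beats every other on (count, then max r2); any tie leaves
    the orphan unassigned.
    """
    samples = ld_sample(study, sample_mode)
    mapped = gmap.df[(gmap.df["method"] != "orphan") & (gmap.df["marker_id"] != orphan)]
    if mapped.empty:
        return LODEPlacement(orphan, None, 0, float("nan"), reason="no framework map")
    pairs = [(orphan, m) for m in mapped["marker_id"]]
    stats = ld_pairs(study, pairs, samples)
    if all(not s.defined for s in stats):
        return LODEPlacement(orphan, None, 0, float("nan"),
                             reason="orphan monomorphic in LD sample")
    r2 = np.array([s.r2 if s.defined else np.nan for s in stats])
    tbl = mapped.assign(r2=r2)
    per_lg = []
    for lg, sub in tbl.groupby("lg", sort=False):
        q = sub[sub["r2"] >= r2_min]
        per_lg.append((lg, len(q), float(q["r2"].max()) if len(q) else float("-inf"), q))
    per_lg.sort(key=lambda t: (-t[1], -t[2]))
    best = per_lg[0]
    if best[1] < min_pairs:
        return LODEPlacement(orphan, None, best[1],
                             best[2] if np.isfinite(best[2]) else float("nan"),
                             reason="fewer than min_pairs qualifying pairs")
    if len(per_lg) > 1:
        second = per_lg[1]
        if second[1] == best[1] and np.isclose(second[2], best[2]):
            return LODEPlacement(orphan, None, best[1], best[2],
                                 reason="tied between linkage groups")
    q = best[3]
    support = list(zip(q["marker_id"], q["r2"], q["pos_sexavg"]))
    return LODEPlacement(orphan, best[0], best[1], best[2], support=support)


def lode_position(placement: LODEPlacement) -> LODEPlacement:
    """Positioning step: r2-weighted mean cM of the qualifying partners."""
    if not placement.assigned or not placement.support:
        return placement
    r2 = np.array([s[1] for s in placement.support], dtype=float)
    pos = np.array([s[2] for s in placement.support], dtype=float)
    placement.position_cM = float((r2 * pos).sum() / r2.sum())
    placement.max_r2_partner_position_cM = float(pos[np.argmax(r2)])
    return placement


def lode_place_all(orphans: Sequence[str], study: GenotypeStudy,
                   gmap: GeneticMapTable, r2_min: float = 0.1,
                   min_pairs: int = 3, sample_mode: str = "parents"
                   ) -> list[LODEPlacement]:
    """Run both LODE steps for every orphan marker."""
    return [lode_position(lode_assign_lg(o, study, gmap, r2_min, min_pairs, sample_mode))
            for o in orphans]


def integrate_lode(gmap: GeneticMapTable, placements: Sequence[LODEPlacement]) -> GeneticMapTable:
    """Insert assigned LODE placements into a map table (method = "lode")."""
    rows = gmap.df.to_dict("records")
    for p in placements:
        if not p.assigned:
            continue
        rows = [r for r in rows if r["marker_id"] != p.marker_id]
        rows.append(dict(marker_id=p.marker_id, lg=p.lg, pos_sexavg=p.position_cM,
                         pos_f=float("nan"), pos_m=float("nan"), method="lode"))
    df = pd.DataFrame(rows).sort_values(["lg", "pos_sexavg"], kind="stable")
    return GeneticMapTable(df.reset_index(drop=True))
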