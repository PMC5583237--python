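"""Heterogeneity and segregation-distortion statistics for linkage maps.

Two likelihood-ratio heterogeneity tests on two-point recombination data
(Ott's goodness-of-fit formulation):

* sex heterogeneity, chi2 = 2 ln(10) [Z_m(theta_m) + Z_f(theta_f)
  - Z(theta_pooled)] on 1 df, asking whether male- and female-derived
  meioses on an interval support different recombination fractions;
* the family M-test, chi2 = 2 ln(10) [sum_i Z_i(theta_i) - Z(theta_pooled)]
  on (families - 1) df, the multi-group generalisation.

Segregation distortion uses the log-likelihood-ratio (G) goodness-of-fit
test against the Mendelian expectation for the cross type (1:1 for a
backcross-type Aa x aa transmission, 1:2:1 for an intercross Aa x Aa).
p-values come from the asymptotic chi-square distribution and are corrected
by Benjamini-Hochberg FDR within each test family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .dataio import MISSING, GenotypeStudy
from .linkage import GeneticMap, PhasedMeioses, TwoPointResult, lod_score

LN10 = math.log(10.0)


@dataclass
class HeterogeneityResult:
    test: str                 # "sex" or "family"
    label: str                # interval / pair id
    chi2: float
    df: int
    p: float
    z_free: float             # Z(theta_m, theta_f) or sum_i Z_i(theta_i)
    z_pooled: float           # Z(theta, theta)
    fdr_q: float = float("nan")
    skipped: bool = False
    reason: str = ""


def _z_at_mle(n: int, r: int) -> float:
    _, z = lod_score(n, r)
    return z


def sex_heterogeneity_test(tp: TwoPointResult, label: Optional[str] = None) -> HeterogeneityResult:
    """Likelihood-ratio test for unequal male/female recombination on a pair."""
    label = label or f"{tp.marker_a}-{tp.marker_b}"
    if tp.n_m < 1 or tp.n_f < 1:
        return HeterogeneityResult("sex", label, float("nan"), 1, float("nan"),
                                   float("nan"), float("nan"), skipped=True,
                                   reason="a sex has zero informative meioses")
    z_free = _z_at_mle(tp.n_m, tp.r_m) + _z_at_mle(tp.n_f, tp.r_f)
    z_pooled = _z_at_mle(tp.n_m + tp.n_f, tp.r_m + tp.r_f)
    chi2 = max(0.0, 2.0 * LN10 * (z_free - z_pooled))
    p = float(sps.chi2.sf(chi2, df=1))
    return HeterogeneityResult("sex", label, chi2, 1, p, z_free, z_pooled)


def family_heterogeneity_mtest(counts: Sequence[tuple[int, int]],
                               label: str = "") -> HeterogeneityResult:
    """M-test across families: (n_i, r_i) per contributing family.

    Families with n_i = 0 are dropped from both the free and pooled terms;
    df = contributing families - 1.
    """
    contributing = [(n, r) for n, r in counts if n > 0]
    if len(contributing) < 2:
        return HeterogeneityResult("family", label, float("nan"), 1, float("nan"),
                                   float("nan"), float("nan"), skipped=True,
                                   reason="fewer than two contributing families")
    z_free = sum(_z_at_mle(n, r) for n, r in contributing)
    n_tot = sum(n for n, _ in contributing)
    r_tot = sum(r for _, r in contributing)
    z_pooled = _z_at_mle(n_tot, r_tot)
    chi2 = max(0.0, 2.0 * LN10 * (z_free - z_pooled))
    df = len(contributing) - 1
    p = float(sps.chi2.sf(chi2, df=df))
    return HeterogeneityResult("family", label, chi2, df, p, z_free, z_pooled)


def heterogeneity_scan(gmap: GeneticMap, phased: PhasedMeioses,
                       test: str = "sex", fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Run the sex or family heterogeneity test over every adjacent interval."""
    from .linkage import twopoint, twopoint_by_family

    results: list[HeterogeneityResult] = []
    for g in gmap.groups:
        for a, b in zip(g.marker_ids[:-1], g.marker_ids[1:]):
            if test == "sex":
                res = sex_heterogeneity_test(twopoint(phased, (a, b)))
            else:
                fam = twopoint_by_family(phased, (a, b), by="family_id")
                res = family_heterogeneity_mtest(
                    list(zip(fam["n"], fam["r"])), label=f"{a}-{b}")
            results.append(res)
    df = pd.DataFrame([r.__dict__ for r in results])
    if len(df):
        ok = ~df["skipped"]
        if ok.any():
            df.loc[ok, "fdr_q"] = bh_fdr(df.loc[ok, "p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# segregation distortion


@dataclass
class DistortionResult:
    marker_id: str
    parent_id: str
    cross_type: str            # "backcross" (Aa x aa/AA) or "intercross" (Aa x Aa)
    observed: tuple
    expected_ratio: tuple
    g_stat: float
    df: int
    p: float
    fdr_q: float = float("nan")
    skipped: bool = False


def g_test(observed: Sequence[float], expected_ratio: Sequence[float]):
    """Log-likelihood-ratio goodness-of-fit: G = 2 sum O ln(O/E).

    Zero observed cells contribute nothing; df = classes - 1.
    """
    obs = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    exp = ratio / ratio.sum() * obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(np.where(obs > 0, obs, 1) / exp), 0.0)
    g = float(2.0 * terms.sum())
    df = len(obs) - 1
    p = float(sps.chi2.sf(g, df=df))
    return g, df, p


def segregation_distortion(study: GenotypeStudy, marker_id: str,
                           parent_id: str) -> DistortionResult:
    """G-test of Mendelian segregation for one informative parent at one marker.

    The parent must be heterozygous.  Against a homozygous mate, progeny
    genotypes split the transmitted allele 1:1; against a heterozygous mate
    the progeny genotype classes follow 1:2:1.
    """
    gm = study.genotypes
    j = gm.marker_col(marker_id)
    gp = gm.codes[gm.sample_row(parent_id), j]
    ped = study.pedigree.df
    as_sire = ped["sire_id"] == parent_id
    as_dam = ped["dam_id"] == parent_id
    kids = ped.loc[as_sire | as_dam]
    if gp != 1 or len(kids) == 0:
        return DistortionResult(marker_id, parent_id, "uninformative", (), (),
                                float("nan"), 0, float("nan"), skipped=True)
    other_ids = np.where(kids["sire_id"] == parent_id, kids["dam_id"], kids["sire_id"])
    child_g = np.array([gm.codes[gm.sample_row(c), j] for c in kids["sample_id"]])
    other_g = np.array([gm.codes[gm.sample_row(o), j] if o and o in gm._srow else MISSING
                        for o in other_ids])
    ok = child_g != MISSING
    # split by mate genotype: homozygous mates give a 1:1 transmission test
    hom_mate = ok & ((other_g == 0) | (other_g == 2))
    het_mate = ok & (other_g == 1)
    if het_mate.sum() >= hom_mate.sum() and het_mate.sum() > 0:
        cg = child_g[het_mate]
        observed = (int((cg == 0).sum()), int((cg == 1).sum()), int((cg == 2).sum()))
        g, df, p = g_test(observed, (1, 2, 1))
        return DistortionResult(marker_id, parent_id, "intercross", observed,
                                (1, 2, 1), g, df, p)
    if hom_mate.sum() > 0:
        cg = child_g[hom_mate]
        og = other_g[hom_mate]
        # transmitted allele from the het parent: child alt count minus mate's contribution
        transmitted = cg - (og // 2)
        observed = (int((transmitted == 0).sum()), int((transmitted == 1).sum()))
        g, df, p = g_test(observed, (1, 1))
        return DistortionResult(marker_id, parent_id, "backcross", observed,
                                (1, 1), g, df, p)
    return DistortionResult(marker_id, parent_id, "uninformative", (), (),
                            float("nan"), 0, float("nan"), skipped=True)


def distortion_scan(study: GenotypeStudy, markers: Optional[Sequence[str]] = None,
                    fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Segregation-distortion G-tests for every informative parent x marker."""
    ped = study.pedigree.df
    parent_ids = sorted(set(ped.loc[ped["sire_id"] != "", "sire_id"])
                        | set(ped.loc[ped["dam_id"] != "", "dam_id"]))
    parent_ids = [p for p in parent_ids if p in study.genotypes._srow]
    markers = list(markers) if markers is not None else study.marker_ids
    rows = []
    for p in parent_ids:
        for m in markers:
            res = segregation_distortion(study, m, p)
            if not res.skipped:
                rows.append(res.__dict__)
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr_q"] = bh_fdr(df["p"].to_numpy())
        df["significant"] = df["fdr_q"] < fdr_alpha
    return df


# ---------------------------------------------------------------------------
# female-to-male map ratios


@dataclass
class SexRatioResult:
    scope: str        # "interval", "lg", "genome"
    label: str
    x_f: float
    x_m: float
    ratio: float      # NaN when undefined (x_m == 0 or a side missing)


def fm_ratios(gmap: GeneticMap) -> list[SexRatioResult]:
    """R = X_f / X_m per interval, per linkage group and genome-wide.

    The genome scope reports both the ratio of totals and the mean of
    per-group ratios (labels ``totals`` and ``mean_of_lgs``); totals are
    over intervals defined in both sexes.
    """
    out: list[SexRatioResult] = []
    lg_ratios = []
    tot_f = tot_m = 0.0
    for g in gmap.groups:
        if g.intervals_f is None or g.intervals_m is None:
            continue
        for k, (a, b) in enumerate(zip(g.marker_ids[:-1], g.marker_ids[1:])):
            xf, xm = g.intervals_f[k], g.intervals_m[k]
            r = xf / xm if np.isfinite(xf) and np.isfinite(xm) and xm > 0 else float("nan")
            out.append(SexRatioResult("interval", f"{g.name}:{a}-{b}", xf, xm, r))
        both = np.isfinite(g.intervals_f) & np.isfinite(g.intervals_m)
        xf = float(g.intervals_f[both].sum())
        xm = float(g.intervals_m[both].sum())
        r = xf / xm if xm > 0 else float("nan")
        out.append(SexRatioResult("lg", g.name, xf, xm, r))
        if np.isfinite(r):
            lg_ratios.append(r)
        tot_f += xf
        tot_m += xm
    out.append(SexRatioResult("genome", "totals", tot_f, tot_m,
                              tot_f / tot_m if tot_m > 0 else float("nan")))
    out.append(SexRatioResult("genome", "mean_of_lgs", tot_f, tot_m,
                              float(np.mean(lg_ratios)) if lg_ratios else float("nan")))
    return out


# ---------------------------------------------------------------------------
# multiple testing


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
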