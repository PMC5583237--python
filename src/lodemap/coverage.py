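"""Genome-coverage estimation and cross-map concordance.

Coverage follows the classic method-of-moments estimator: each linkage
group's expected genome length is Ge = L * (m + 1) / (m - 1), where L is
its observed cM length and m its marker count; genome coverage is
Coa = Goa / Ge_total with Goa the sum of observed lengths.  Cross-map
comparisons build an Oxford grid — the contingency matrix of shared-marker
counts over (group of map A x group of map B) — from which majority-rule
group matches, discordant markers and merge/split candidates are derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .dataio import CorrespondenceTable, GeneticMapTable
from .errors import IntegrityError


@dataclass
class CoverageReport:
    """Per-group observed and expected lengths plus map-wide totals."""

    per_lg: pd.DataFrame   # columns: lg, length_cM, n_markers, ge_cM, flagged
    goa: float             # total observed length
    ge_total: float        # total expected genome length (over unflagged LGs)

    @property
    def coverage_pct(self) -> float:
        if self.ge_total == 0:
            return float("nan")
        return 100.0 * self.goa / self.ge_total


def expected_lg_length(length_cM: float, n_markers: int) -> float:
    """Ge = L (m + 1) / (m - 1); requires m >= 2 (m >= 3 for a meaningful value)."""
    if n_markers < 2:
        raise IntegrityError("Ge needs at least two markers")
    return length_cM * (n_markers + 1) / (n_markers - 1)


def expected_genome_length(lengths: Sequence[float], counts: Sequence[int],
                           lgs: Optional[Sequence[str]] = None) -> CoverageReport:
    """Per-group Ge and totals from observed lengths and marker counts.

    Groups with fewer than two markers are excluded and flagged; groups
    with exactly two get a Ge but carry a flag since the estimator only
    becomes meaningful from three markers.
    """
    if len(lengths) != len(counts):
        raise IntegrityError("lengths and counts disagree in length")
    lgs = list(lgs) if lgs is not None else [f"LG{k + 1}" for k in range(len(lengths))]
    rows = []
    for lg, L, m in zip(lgs, lengths, counts):
        if m < 2:
            rows.append(dict(lg=lg, length_cM=L, n_markers=m, ge_cM=float("nan"),
                             flagged=True))
            continue
        rows.append(dict(lg=lg, length_cM=L, n_markers=m,
                         ge_cM=expected_lg_length(L, m), flagged=m == 2))
    df = pd.DataFrame(rows)
    usable = df["ge_cM"].notna()
    goa = float(df.loc[usable, "length_cM"].sum())
    ge_total = float(df.loc[usable, "ge_cM"].sum())
    return CoverageReport(df, goa, ge_total)


def coverage_from_map(gmap: GeneticMapTable) -> CoverageReport:
    """Coverage report from a built map table (sex-average lengths).

    m counts all placed markers, co-localised ones included.
    """
    mapped = gmap.df[gmap.df["method"] != "orphan"]
    lengths, counts, lgs = [], [], []
    for lg, sub in mapped.groupby("lg", sort=False):
        lgs.append(lg)
        lengths.append(float(sub["pos_sexavg"].max() - sub["pos_sexavg"].min()))
        counts.append(len(sub))
    return expected_genome_length(lengths, counts, lgs)


def genome_coverage(report: CoverageReport) -> float:
    """Coa = Goa / Ge_total, as a percentage."""
    return report.coverage_pct


# ---------------------------------------------------------------------------
# Oxford grids


@dataclass
class OxfordGrid:
    """Shared-marker counts over (map-A group x map-B group)."""

    matrix: pd.DataFrame          # index: lg_a, columns: lg_b
    marker_detail: pd.DataFrame   # marker_a, marker_b, lg_a, lg_b, concordant
    n_skipped: int

    @property
    def n_shared(self) -> int:
        return int(self.matrix.to_numpy().sum())

    def discordant_markers(self) -> pd.DataFrame:
        return self.marker_detail[~self.marker_detail["concordant"]]


def oxford_grid(correspondence: CorrespondenceTable,
                map_a: Optional[GeneticMapTable] = None,
                map_b: Optional[GeneticMapTable] = None) -> OxfordGrid:
    """Build the Oxford grid from a correspondence table.

    When map tables are supplied, rows whose markers are absent from them
    are skipped (and counted); otherwise the table's own group labels are
    trusted.  A marker is concordant iff it sits in the majority cell of
    its map-A group.
    """
    df = correspondence.df.copy()
    n_skipped = 0
    if map_a is not None:
        known = set(map_a.df["marker_id"])
        before = len(df)
        df = df[df["marker_a"].isin(known)]
        n_skipped += before - len(df)
    if map_b is not None:
        known = set(map_b.df["marker_id"])
        before = len(df)
        df = df[df["marker_b"].isin(known)]
        n_skipped += before - len(df)
    if df.empty:
        return OxfordGrid(pd.DataFrame(), df.assign(concordant=pd.Series(dtype=bool)),
                          n_skipped)
    matrix = pd.crosstab(df["lg_a"], df["lg_b"])
    majority_b = matrix.idxmax(axis=1)
    detail = df[["marker_a", "marker_b", "lg_a", "lg_b"]].copy()
    detail["concordant"] = [
        r.lg_b == majority_b[r.lg_a] for r in detail.itertuples()
    ]
    return OxfordGrid(matrix, detail.reset_index(drop=True), n_skipped)


@dataclass
class LGMatchReport:
    """Majority-rule group matching with merge/split flags."""

    matches: pd.DataFrame           # lg_a, matched_lg_b, n_support, n_discordant
    merge_candidates: pd.DataFrame  # lg_a, lg_b_list (>=2 B-groups on one A-group)
    split_candidates: pd.DataFrame  # lg_b, lg_a_list


def lg_match(grid: OxfordGrid, min_markers: int = 2) -> LGMatchReport:
    """Match groups across maps by majority rule.

    A merge candidate arises when at least two map-B groups each place
    ``min_markers`` shared markers on one map-A group (the B-groups may be
    one chromosome split in map B); split candidates are symmetric.
    """
    m = grid.matrix
    if m.empty:
        empty = pd.DataFrame()
        return LGMatchReport(empty, empty, empty)
    rows = []
    for lg_a in m.index:
        counts = m.loc[lg_a]
        best = counts.idxmax()
        support = int(counts[best])
        total = int(counts.sum())
        matched = best if support * 2 >= total and support > 0 else None
        rows.append(dict(lg_a=lg_a, matched_lg_b=matched, n_support=support,
                         n_discordant=total - support))
    merges = []
    for lg_a in m.index:
        heavy = [lg_b for lg_b in m.columns if m.loc[lg_a, lg_b] >= min_markers]
        if len(heavy) >= 2:
            merges.append(dict(lg_a=lg_a, lg_b_list=sorted(heavy)))
    splits = []
    for lg_b in m.columns:
        heavy = [lg_a for lg_a in m.index if m.loc[lg_a, lg_b] >= min_markers]
        if len(heavy) >= 2:
            splits.append(dict(lg_b=lg_b, lg_a_list=sorted(heavy)))
    return LGMatchReport(pd.DataFrame(rows),
                         pd.DataFrame(merges, columns=["lg_a", "lg_b_list"]),
                         pd.DataFrame(splits, columns=["lg_b", "lg_a_list"]))


def plot_oxford_grid(grid: OxfordGrid, path: str) -> None:
    """Render the grid as a dot-size matrix (optional convenience)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = grid.matrix
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * m.shape[1]), max(4, 0.3 * m.shape[0])))
    ys, xs, sizes = [], [], []
    for i, lg_a in enumerate(m.index):
        for j, lg_b in enumerate(m.columns):
            if m.iloc[i, j] > 0:
                ys.append(i)
                xs.append(j)
                sizes.append(20 * m.iloc[i, j])
    ax.scatter(xs, ys, s=sizes)
    ax.set_xticks(range(m.shape[1]), m.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(m.shape[0]), m.index, fontsize=6)
    ax.set_xlabel("map B linkage group")
    ax.set_ylabel("map A linkage group")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
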