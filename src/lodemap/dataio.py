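"""Readers, writers and validated in-memory containers for study tables.

Genotypes are held unphased as alt-allele counts (0, 1, 2; -1 = missing);
phase is always derived downstream from grandparent-traced pedigrees.
Two on-disk dialects are supported: a PLINK-style space-delimited PED/MAP
pair ("0" = missing allele) and a simple TSV with one column per marker
(cells in {0, 1, 2, NA}).  Map coordinates are centimorgans, zero-based at
the first marker of each linkage group.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

MISSING = -1

PEDIGREE_COLUMNS = ["sample_id", "sire_id", "dam_id", "sex", "family_id", "generation"]
MAP_COLUMNS = ["marker_id", "lg", "pos_sexavg", "pos_f", "pos_m", "method"]
CORRESPONDENCE_COLUMNS = ["marker_a", "marker_b", "lg_a", "pos_a", "lg_b", "pos_b"]

VALID_SEX = {"M", "F", "U"}
VALID_GENERATION = {"grandparent", "parent", "progeny"}
VALID_PLACEMENT = {"linkage", "lode", "orphan"}


@dataclass(frozen=True)
class MarkerDef:
    """Identity and allele coding of one bi-allelic SNP.

    ``alleles`` orders (ref, alt); genotype codes count copies of the alt
    allele.  ``flags`` carries upstream array annotations (e.g. from
    clustering software) that the QC pipeline consumes but never computes.
    """

    marker_id: str
    alleles: tuple[str, str] = ("A", "B")
    source_contig: Optional[str] = None
    lg_hint: Optional[str] = None
    pos_hint: Optional[float] = None
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.alleles[0] == self.alleles[1]:
            raise IntegrityError(f"marker {self.marker_id}: alleles must be distinct")


class PedigreeTable:
    """Sample relationships: (sample, sire, dam, sex, family, generation).

    Unknown parents are stored as the empty string.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in PEDIGREE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"pedigree missing columns: {missing}")
        df = df[PEDIGREE_COLUMNS].astype(str)
        df[["sire_id", "dam_id"]] = df[["sire_id", "dam_id"]].replace(
            {"0": "", "nan": "", "<NA>": "", "None": ""}
        )
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise IntegrityError(f"duplicate sample_id(s): {dups[:5]}")
        bad_sex = set(df["sex"]) - VALID_SEX
        if bad_sex:
            raise FormatError(f"invalid sex codes: {sorted(bad_sex)}")
        bad_gen = set(df["generation"]) - VALID_GENERATION
        if bad_gen:
            raise FormatError(f"invalid generation labels: {sorted(bad_gen)}")
        self.df = df.reset_index(drop=True)
        self._check_ancestry()

    def _check_ancestry(self) -> None:
        parent_of = {
            r.sample_id: {p for p in (r.sire_id, r.dam_id) if p}
            for r in self.df.itertuples()
        }
        for start in parent_of:
            seen: set[str] = set()
            frontier = set(parent_of.get(start, ()))
            while frontier:
                if start in frontier:
                    raise IntegrityError(f"sample {start} is its own ancestor")
                seen |= frontier
                frontier = {
                    g for p in frontier for g in parent_of.get(p, ()) if g not in seen
                }

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    def rows(self):
        return self.df.itertuples(index=False)

    def parents_of(self, sample_id: str) -> tuple[str, str]:
        r = self.df.loc[self.df["sample_id"] == sample_id].iloc[0]
        return r["sire_id"], r["dam_id"]

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, PedigreeTable) and self.df.equals(other.df)


class GenotypeMatrix:
    """samples x markers alt-allele-count codes; -1 encodes missing."""

    def __init__(self, codes: np.ndarray, sample_ids: Sequence[str], marker_ids: Sequence[str]):
        codes = np.asarray(codes, dtype=np.int8)
        if codes.ndim != 2:
            raise FormatError("genotype codes must be a 2-D array")
        if codes.shape != (len(sample_ids), len(marker_ids)):
            raise FormatError(
                f"genotype matrix {codes.shape} does not match "
                f"{len(sample_ids)} samples x {len(marker_ids)} markers"
            )
        legal = np.isin(codes, (MISSING, 0, 1, 2))
        if not legal.all():
            i, j = np.argwhere(~legal)[0]
            raise FormatError(
                f"illegal genotype code {codes[i, j]} at sample row {i}, marker column {j}"
            )
        if len(set(marker_ids)) != len(marker_ids):
            raise IntegrityError("duplicate marker column in genotype matrix")
        if len(set(sample_ids)) != len(sample_ids):
            raise IntegrityError("duplicate sample row in genotype matrix")
        self.codes = codes
        self.sample_ids = list(sample_ids)
        self.marker_ids = list(marker_ids)
        self._srow = {s: i for i, s in enumerate(self.sample_ids)}
        self._mcol = {m: j for j, m in enumerate(self.marker_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def sample_row(self, sample_id: str) -> int:
        return self._srow[sample_id]

    def marker_col(self, marker_id: str) -> int:
        return self._mcol[marker_id]

    def genotype(self, sample_id: str, marker_id: str) -> int:
        return int(self.codes[self._srow[sample_id], self._mcol[marker_id]])

    def n_missing(self) -> int:
        return int((self.codes == MISSING).sum())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.sample_ids == other.sample_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.codes, other.codes)
        )


@dataclass
class GenotypeStudy:
    """The pipeline working set: markers + pedigree + genotypes + metadata."""

    markers: list[MarkerDef]
    pedigree: PedigreeTable
    genotypes: GenotypeMatrix
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        marker_ids = [m.marker_id for m in self.markers]
        if len(set(marker_ids)) != len(marker_ids):
            raise IntegrityError("duplicate marker_id in marker list")
        if marker_ids != self.genotypes.marker_ids:
            raise IntegrityError("marker list and genotype columns disagree")
        if self.pedigree.sample_ids != self.genotypes.sample_ids:
            raise IntegrityError("pedigree samples and genotype rows disagree")

    @property
    def marker_ids(self) -> list[str]:
        return self.genotypes.marker_ids

    @property
    def sample_ids(self) -> list[str]:
        return self.genotypes.sample_ids

    def subset_markers(self, keep: Iterable[str]) -> "GenotypeStudy":
        keep = list(keep)
        cols = [self.genotypes.marker_col(m) for m in keep]
        markers = [self.markers[c] for c in cols]
        gm = GenotypeMatrix(self.genotypes.codes[:, cols], self.sample_ids, keep)
        return GenotypeStudy(markers, self.pedigree, gm, dict(self.metadata))

    def subset_samples(self, keep: Iterable[str]) -> "GenotypeStudy":
        keep = list(keep)
        rows = [self.genotypes.sample_row(s) for s in keep]
        gm = GenotypeMatrix(self.genotypes.codes[rows, :], keep, self.marker_ids)
        ped = PedigreeTable(
            self.pedigree.df[self.pedigree.df["sample_id"].isin(keep)]
            .set_index("sample_id")
            .loc[keep]
            .reset_index()
        )
        return GenotypeStudy(list(self.markers), ped, gm, dict(self.metadata))


class GeneticMapTable:
    """Ordered markers per linkage group with sex-average / female / male cM."""

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in MAP_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"map table missing columns: {missing}")
        df = df[MAP_COLUMNS]
        for c in ("pos_sexavg", "pos_f", "pos_m"):
            df[c] = pd.to_numeric(df[c], errors="raise")
        bad_method = set(df["method"]) - VALID_PLACEMENT
        if bad_method:
            raise FormatError(f"invalid placement method(s): {sorted(bad_method)}")
        if (df["pos_sexavg"].dropna() < 0).any():
            raise IntegrityError("negative sex-average map position")
        for lg, sub in df.groupby("lg", sort=False):
            pos = sub["pos_sexavg"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise IntegrityError(f"LG {lg}: sex-average positions not non-decreasing")
        if df["marker_id"].duplicated().any():
            raise IntegrityError("duplicate marker_id in map table")
        self.df = df.reset_index(drop=True)

    @property
    def linkage_groups(self) -> list[str]:
        return list(dict.fromkeys(self.df["lg"]))

    def markers_on(self, lg: str) -> list[str]:
        return self.df.loc[self.df["lg"] == lg, "marker_id"].tolist()

    def position(self, marker_id: str) -> float:
        return float(self.df.loc[self.df["marker_id"] == marker_id, "pos_sexavg"].iloc[0])

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneticMapTable):
            return False
        a, b = self.df, other.df
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            if a[c].dtype.kind == "f":
                ok = np.allclose(a[c], b[c], equal_nan=True)
            else:
                ok = (a[c] == b[c]).all()
            if not ok:
                return False
        return True


class CorrespondenceTable:
    """Marker pairs shared between two maps, with positions on each."""

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in CORRESPONDENCE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"correspondence table missing columns: {missing}")
        df = df[CORRESPONDENCE_COLUMNS]
        for c in ("pos_a", "pos_b"):
            try:
                df[c] = pd.to_numeric(df[c], errors="raise")
            except (ValueError, TypeError) as exc:
                raise FormatError(f"non-numeric cM in column {c}") from exc
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# genotype study I/O


def _sex_to_ped(sex: str) -> str:
    return {"M": "1", "F": "2", "U": "0"}[sex]


def _sex_from_ped(code: str) -> str:
    return {"1": "M", "2": "F"}.get(code, "U")


def _infer_generation(ped: pd.DataFrame) -> pd.Series:
    """PED files carry no generation column; classify by pedigree topology."""
    children: dict[str, list[str]] = {}
    for r in ped.itertuples():
        for p in (r.sire_id, r.dam_id):
            if p:
                children.setdefault(p, []).append(r.sample_id)
    is_parent = ped["sample_id"].isin(children)
    parent_of_parent = ped["sample_id"].map(
        lambda s: any(c in children for c in children.get(s, ()))
    )
    gen = pd.Series("progeny", index=ped.index)
    gen[is_parent] = "parent"
    gen[parent_of_parent] = "grandparent"
    return gen


def read_genotypes(path: str, dialect: str = "tsv", pedigree_path: Optional[str] = None) -> GenotypeStudy:
    """Load a genotype study.

    ``dialect="ped_map"`` expects ``path`` to be a basename with ``.ped`` and
    ``.map`` siblings; ``dialect="tsv"`` expects a genotype TSV plus a
    pedigree TSV given via ``pedigree_path``.
    """
    if dialect == "ped_map":
        return _read_ped_map(path)
    if dialect == "tsv":
        if pedigree_path is None:
            raise FormatError("tsv dialect requires pedigree_path")
        return _read_tsv(path, pedigree_path)
    raise FormatError(f"unknown genotype dialect: {dialect}")


def _read_ped_map(basename: str) -> GenotypeStudy:
    ped_path, map_path = basename + ".ped", basename + ".map"
    for p in (ped_path, map_path):
        if not os.path.exists(p):
            raise FormatError(f"missing file: {p}")
    map_df = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "marker_id", "genetic_pos", "bp_pos"], dtype=str,
    )
    if map_df["marker_id"].duplicated().any():
        raise IntegrityError("duplicate marker_id in MAP file")
    marker_ids = map_df["marker_id"].tolist()
    n_markers = len(marker_ids)

    rows, ped_rows, allele_pairs = [], [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_markers:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_markers} fields, got {len(fields)}"
                )
            fam, iid, sire, dam, sex, _pheno = fields[:6]
            ped_rows.append(
                dict(sample_id=iid, sire_id="" if sire == "0" else sire,
                     dam_id="" if dam == "0" else dam, sex=_sex_from_ped(sex),
                     family_id=fam, generation="progeny")
            )
            allele_pairs.append(fields[6:])
            rows.append(iid)
    if len(set(rows)) != len(rows):
        raise IntegrityError("duplicate sample_id in PED file")

    # establish per-marker allele coding from observed alleles ("0" = missing)
    observed: list[dict[str, int]] = [dict() for _ in range(n_markers)]
    for pair_row in allele_pairs:
        for j in range(n_markers):
            for a in (pair_row[2 * j], pair_row[2 * j + 1]):
                if a != "0":
                    observed[j][a] = observed[j].get(a, 0) + 1
    markers = []
    coding: list[dict[str, int]] = []
    for j, mid in enumerate(marker_ids):
        alleles = sorted(observed[j], key=lambda a: (-observed[j][a], a))
        if len(alleles) > 2:
            raise FormatError(f"marker {mid}: more than two alleles in PED file")
        while len(alleles) < 2:
            alleles.append("B" if "B" not in alleles else "A")
        ref, alt = alleles[0], alleles[1]
        pos_hint = float(map_df["genetic_pos"].iloc[j]) if map_df["genetic_pos"].iloc[j] not in ("0", "-9") else None
        lg_hint = map_df["chrom"].iloc[j] if map_df["chrom"].iloc[j] != "0" else None
        markers.append(MarkerDef(mid, (ref, alt), lg_hint=lg_hint, pos_hint=pos_hint))
        coding.append({ref: 0, alt: 1})

    codes = np.full((len(rows), n_markers), MISSING, dtype=np.int8)
    for i, pair_row in enumerate(allele_pairs):
        for j in range(n_markers):
            a1, a2 = pair_row[2 * j], pair_row[2 * j + 1]
            if a1 == "0" or a2 == "0":
                continue
            c1, c2 = coding[j].get(a1), coding[j].get(a2)
            if c1 is None or c2 is None:  # unknown allele code -> missing
                continue
            codes[i, j] = c1 + c2

    ped_df = pd.DataFrame(ped_rows)
    ped_df["generation"] = _infer_generation(ped_df)
    pedigree = PedigreeTable(ped_df)
    gm = GenotypeMatrix(codes, rows, marker_ids)
    return GenotypeStudy(markers, pedigree, gm, {"source": basename, "dialect": "ped_map"})


def _read_tsv(genotype_path: str, pedigree_path: str) -> GenotypeStudy:
    for p in (genotype_path, pedigree_path):
        if not os.path.exists(p):
            raise FormatError(f"missing file: {p}")
    with open(genotype_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "sample_id":
        raise FormatError("genotype TSV must start with a sample_id column")
    marker_ids = header[1:]
    if len(set(marker_ids)) != len(marker_ids):
        raise IntegrityError("duplicated marker column in genotype TSV")
    raw = pd.read_csv(genotype_path, sep="\t", dtype=str, keep_default_na=False)
    raw.columns = header
    sample_ids = raw["sample_id"].astype(str).tolist()
    body = raw[marker_ids].replace({"NA": str(MISSING), "": str(MISSING)})
    try:
        codes = body.to_numpy(dtype=float).astype(np.int8)
    except ValueError as exc:
        raise FormatError(f"non-numeric genotype cell in {genotype_path}") from exc
    pedigree = read_pedigree(pedigree_path)
    markers = [MarkerDef(m) for m in marker_ids]
    gm = GenotypeMatrix(codes, sample_ids, marker_ids)
    return GenotypeStudy(markers, pedigree, gm, {"source": genotype_path, "dialect": "tsv"})


def write_genotypes(study: GenotypeStudy, path: str, dialect: str = "tsv",
                    pedigree_path: Optional[str] = None) -> None:
    if dialect == "tsv":
        df = pd.DataFrame(study.genotypes.codes, columns=study.marker_ids)
        df = df.astype(object).where(df != MISSING, "NA")
        df.insert(0, "sample_id", study.sample_ids)
        df.to_csv(path, sep="\t", index=False)
        if pedigree_path:
            write_pedigree(study.pedigree, pedigree_path)
        return
    if dialect == "ped_map":
        _write_ped_map(study, path)
        return
    raise FormatError(f"unknown genotype dialect: {dialect}")


def _write_ped_map(study: GenotypeStudy, basename: str) -> None:
    with open(basename + ".map", "w") as fh:
        for m in study.markers:
            fh.write(
                f"{m.lg_hint or 0} {m.marker_id} "
                f"{m.pos_hint if m.pos_hint is not None else 0} 0\n"
            )
    codes = study.genotypes.codes
    alleles = [(m.alleles[0], m.alleles[1]) for m in study.markers]
    with open(basename + ".ped", "w") as fh:
        for r in study.pedigree.rows():
            i = study.genotypes.sample_row(r.sample_id)
            fields = [r.family_id, r.sample_id, r.sire_id or "0", r.dam_id or "0",
                      _sex_to_ped(r.sex), "-9"]
            for j, (ref, alt) in enumerate(alleles):
                c = codes[i, j]
                if c == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [ref if c < 2 else alt, alt if c > 0 else ref]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# pedigree / map / correspondence I/O


def read_pedigree(path: str) -> PedigreeTable:
    if not os.path.exists(path):
        raise FormatError(f"missing file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return PedigreeTable(df)


def write_pedigree(ped: PedigreeTable, path: str) -> None:
    ped.df.to_csv(path, sep="\t", index=False)


def read_map(path: str) -> GeneticMapTable:
    if not os.path.exists(path):
        raise FormatError(f"missing file: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "lg": str, "method": str})
    return GeneticMapTable(df)


def write_map(gmap: GeneticMapTable, path: str) -> None:
    gmap.df.to_csv(path, sep="\t", index=False)


def read_correspondence(path: str) -> CorrespondenceTable:
    if not os.path.exists(path):
        raise FormatError(f"missing file: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"marker_a": str, "marker_b": str,
                                            "lg_a": str, "lg_b": str})
    return CorrespondenceTable(df)


def write_correspondence(table: CorrespondenceTable, path: str) -> None:
    table.df.to_csv(path, sep="\t", index=False)
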