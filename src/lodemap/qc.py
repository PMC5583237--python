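"""Marker/sample QC, exclusion-ledger accounting and parent reconstruction.

Implements the array-performance bookkeeping used for SNP-array validation:
per-marker summary statistics (call rate, MAF, exact-test HWE on parents,
Mendelian agreement), a strictly ordered exclusion ledger whose derived
rates (conversion, validation, minimal-error, final) all use the number of
genotype-producing SNPs as denominator, the in-silico candidate-SNP filter
ledger, and a per-locus maximum-likelihood reconstruction of an ungenotyped
parent from its mate and progeny.

Mendelian agreement per marker is 1 - (Mendelian errors / loci genotyped);
an error is a progeny genotype impossible given the available parent
genotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .dataio import MISSING, GenotypeStudy
from .errors import IntegrityError

# ---------------------------------------------------------------------------
# exact HWE test


def hwe_exact_test(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test (two-sided, Wigginton-style).

    Sums the conditional probabilities of all heterozygote counts no more
    probable than the observed one, given the allele counts.
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return float("nan")
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # conditional distribution of heterozygote count given allele counts
    hets = range(n_rare % 2, n_rare + 1, 2)
    logprob = {}
    for h in hets:
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        if common_hom < 0:
            continue
        lp = (math.lgamma(n + 1) - math.lgamma(h + 1) - math.lgamma(rare_hom + 1)
              - math.lgamma(common_hom + 1) + h * math.log(2)
              + math.lgamma(n_rare + 1) + math.lgamma(2 * n - n_rare + 1)
              - math.lgamma(2 * n + 1))
        logprob[h] = lp
    mx = max(logprob.values())
    probs = {h: math.exp(lp - mx) for h, lp in logprob.items()}
    total = sum(probs.values())
    obs = probs.get(n_het, 0.0)
    p = sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total
    return min(1.0, p)


# ---------------------------------------------------------------------------
# per-marker summary


@dataclass
class SNPSummary:
    marker_id: str
    call_rate: float
    maf: float
    het_frequency: float
    hwe_p: float
    n_mendelian_errors: int
    n_loci_tested: int
    mendelian_agreement: float
    flags: set[str] = field(default_factory=set)


def _parent_mask(study: GenotypeStudy) -> np.ndarray:
    gen = study.pedigree.df["generation"].to_numpy()
    return np.isin(gen, ("grandparent", "parent"))


def snp_summary(study: GenotypeStudy, hwe_alpha: float = 1e-4) -> list[SNPSummary]:
    """Per-marker call rate, MAF, het frequency, exact HWE (parents only),
    Mendelian agreement, and QC flags."""
    codes = study.genotypes.codes
    n_samples = codes.shape[0]
    if n_samples == 0:
        raise IntegrityError("study has no samples")
    parents = _parent_mask(study)
    errors, tested = mendelian_error_counts(study)
    out = []
    for j, m in enumerate(study.markers):
        col = codes[:, j]
        called = col != MISSING
        call_rate = called.sum() / n_samples
        flags = set(m.flags)
        if called.sum() == 0:
            out.append(SNPSummary(m.marker_id, 0.0, float("nan"), float("nan"),
                                  float("nan"), 0, 0, float("nan"),
                                  flags | {"no_amplify", "undefined"}))
            continue
        alt = col[called].astype(float).sum() / (2 * called.sum())
        maf = min(alt, 1 - alt)
        het = (col[called] == 1).mean()
        pcol = col[parents]
        pcalled = pcol != MISSING
        if pcalled.sum() > 0:
            n_het = int((pcol[pcalled] == 1).sum())
            n0 = int((pcol[pcalled] == 0).sum())
            n2 = int((pcol[pcalled] == 2).sum())
            hwe_p = hwe_exact_test(n_het, n0, n2)
        else:
            hwe_p = float("nan")
        if het == 0.0:
            flags.add("monomorphic")
        if maf < 0.01:
            flags.add("low_maf")
        if not math.isnan(hwe_p) and hwe_p < hwe_alpha:
            flags.add("hwe_fail")
        agreement = (1.0 - errors[j] / tested[j]) if tested[j] > 0 else float("nan")
        out.append(SNPSummary(m.marker_id, float(call_rate), float(maf), float(het),
                              float(hwe_p), int(errors[j]), int(tested[j]),
                              agreement, flags))
    return out


# ---------------------------------------------------------------------------
# Mendelian agreement

def _transmission_possible(parent: int, allele: int) -> bool:
    """Can a parent of given alt-count transmit the given allele (0/1)?"""
    if parent == 0:
        return allele == 0
    if parent == 2:
        return allele == 1
    return True


def trio_consistent(p1: int, p2: int, child: int) -> bool:
    """Is the child genotype possible given available parent genotypes?

    MISSING parents are unconstrained.
    """
    if child == MISSING:
        return True
    child_pairs = {0: [(0, 0)], 1: [(0, 1), (1, 0)], 2: [(1, 1)]}[child]
    for a1, a2 in child_pairs:
        ok1 = p1 == MISSING or _transmission_possible(p1, a1)
        ok2 = p2 == MISSING or _transmission_possible(p2, a2)
        if ok1 and ok2:
            return True
    return False


def mendelian_error_counts(study: GenotypeStudy,
                           trios: Optional[Sequence[tuple[str, str, str]]] = None):
    """Per-marker Mendelian error and tested-locus counts over trios.

    ``trios`` is (child, sire, dam); by default every pedigree row with at
    least one genotyped parent contributes.  A locus counts as tested when
    the child and at least one parent are genotyped there.
    """
    gm = study.genotypes
    codes = gm.codes
    n_markers = codes.shape[1]
    errors = np.zeros(n_markers, dtype=int)
    tested = np.zeros(n_markers, dtype=int)
    if trios is None:
        trios = []
        for r in study.pedigree.rows():
            if (r.sire_id and r.sire_id in gm._srow) or (r.dam_id and r.dam_id in gm._srow):
                trios.append((r.sample_id, r.sire_id, r.dam_id))
    for child, sire, dam in trios:
        c = codes[gm.sample_row(child)]
        s = codes[gm.sample_row(sire)] if sire and sire in gm._srow else np.full(n_markers, MISSING, dtype=np.int8)
        d = codes[gm.sample_row(dam)] if dam and dam in gm._srow else np.full(n_markers, MISSING, dtype=np.int8)
        child_ok = c != MISSING
        any_parent = (s != MISSING) | (d != MISSING)
        use = child_ok & any_parent
        tested += use.astype(int)
        # vectorised impossibility test
        err = np.zeros(n_markers, dtype=bool)
        # child hom: each parent must be able to transmit that allele
        err |= use & (c == 0) & ((s == 2) | (d == 2))
        err |= use & (c == 2) & ((s == 0) | (d == 0))
        # child het: impossible only if both parents are the same homozygote
        err |= use & (c == 1) & (((s == 0) & (d == 0)) | ((s == 2) & (d == 2)))
        errors += err.astype(int)
    return errors, tested


def mask_mendelian_errors(study: GenotypeStudy) -> GenotypeStudy:
    """Set progeny genotypes inconsistent with their parents to missing.

    Isolated genotyping errors that violate Mendelian transmission would
    otherwise masquerade as double recombinants and inflate map lengths;
    masking the cell keeps the meiosis uninformative at that marker only.
    """
    gm = study.genotypes
    codes = gm.codes.copy()
    n_markers = codes.shape[1]
    for r in study.pedigree.rows():
        if not (r.sire_id or r.dam_id):
            continue
        c = codes[gm.sample_row(r.sample_id)]
        s = codes[gm.sample_row(r.sire_id)] if r.sire_id and r.sire_id in gm._srow \
            else np.full(n_markers, MISSING, dtype=np.int8)
        d = codes[gm.sample_row(r.dam_id)] if r.dam_id and r.dam_id in gm._srow \
            else np.full(n_markers, MISSING, dtype=np.int8)
        bad = np.zeros(n_markers, dtype=bool)
        bad |= (c == 0) & ((s == 2) | (d == 2))
        bad |= (c == 2) & ((s == 0) | (d == 0))
        bad |= (c == 1) & (((s == 0) & (d == 0)) | ((s == 2) & (d == 2)))
        if bad.any():
            codes[gm.sample_row(r.sample_id), bad] = MISSING
    out = GenotypeStudy(list(study.markers), study.pedigree,
                        type(gm)(codes, gm.sample_ids, gm.marker_ids),
                        dict(study.metadata))
    return out


def mendelian_agreement(study: GenotypeStudy,
                        trios: Optional[Sequence[tuple[str, str, str]]] = None) -> pd.Series:
    """Per-marker agreement = 1 - errors / loci tested (NaN when untested)."""
    errors, tested = mendelian_error_counts(study, trios)
    with np.errstate(invalid="ignore", divide="ignore"):
        agreement = np.where(tested > 0, 1.0 - errors / np.maximum(tested, 1), np.nan)
    return pd.Series(agreement, index=study.marker_ids, name="mendelian_agreement")


# ---------------------------------------------------------------------------
# duplicate detection


def detect_duplicates(study: GenotypeStudy, concordance_threshold: float = 0.995):
    """Marker pairs whose non-missing genotype concordance meets the threshold.

    Returns (pairs, flagged) where ``flagged`` is the later-listed member of
    each duplicate pair.
    """
    codes = study.genotypes.codes
    ids = study.marker_ids
    n_markers = len(ids)
    pairs, flagged = [], set()
    called = codes != MISSING
    for i in range(n_markers):
        for j in range(i + 1, n_markers):
            both = called[:, i] & called[:, j]
            n = int(both.sum())
            if n == 0:
                continue
            conc = float((codes[both, i] == codes[both, j]).mean())
            if conc >= concordance_threshold:
                pairs.append((ids[i], ids[j], conc))
                flagged.add(ids[j])
    return pairs, sorted(flagged)


# ---------------------------------------------------------------------------
# exclusion ledger


@dataclass
class QCLedger:
    """Ordered exclusion steps with the derived array-performance rates.

    Rates follow array-validation convention: the conversion rate divides
    the genotype-producing SNP count by the full array content, while the
    validation, minimal-error and final ("no errors") rates all divide by
    the genotype-producing count.
    """

    start_label: str
    start_count: int
    steps: list[tuple[str, int, int]] = field(default_factory=list)  # label, excluded, remaining

    def add(self, label: str, n_excluded: int) -> None:
        prev = self.steps[-1][2] if self.steps else self.start_count
        if n_excluded < 0 or n_excluded > prev:
            raise IntegrityError(f"step {label}: invalid exclusion count {n_excluded}")
        self.steps.append((label, int(n_excluded), int(prev - n_excluded)))

    @classmethod
    def from_counts(cls, start_count: int, counts: Sequence[tuple[str, int]],
                    start_label: str = "total") -> "QCLedger":
        ledger = cls(start_label, int(start_count))
        for label, n in counts:
            ledger.add(label, n)
        return ledger

    def remaining_after(self, label: str) -> int:
        for lab, _, rem in self.steps:
            if lab == label:
                return rem
        raise KeyError(label)

    @property
    def final_count(self) -> int:
        return self.steps[-1][2] if self.steps else self.start_count

    def _checkpoint(self, labels: Iterable[str]) -> Optional[int]:
        got = None
        for lab, _, rem in self.steps:
            if lab in labels:
                got = rem
        return got

    @property
    def n_genotyped(self) -> Optional[int]:
        return self._checkpoint({"ambiguous", "no_amplify"})

    @property
    def conversion_rate(self) -> float:
        return 100.0 * self.n_genotyped / self.start_count

    @property
    def validation_rate(self) -> float:
        return 100.0 * self._checkpoint({"monomorphic"}) / self.n_genotyped

    @property
    def minimal_error_rate(self) -> float:
        return 100.0 * self._checkpoint({"mi", "mendelian"}) / self.n_genotyped

    @property
    def final_rate(self) -> float:
        return 100.0 * self.final_count / self.n_genotyped

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(step=0, label=self.start_label, n_excluded=0,
                     n_remaining=self.start_count)]
        for k, (lab, ex, rem) in enumerate(self.steps, 1):
            rows.append(dict(step=k, label=lab, n_excluded=ex, n_remaining=rem))
        return pd.DataFrame(rows)

    def conserved(self) -> bool:
        return self.start_count == self.final_count + sum(ex for _, ex, _ in self.steps)


@dataclass
class QCThresholds:
    sample_call_rate: float = 0.90
    marker_call_rate: float = 0.90
    maf: float = 0.01
    hwe_alpha: float = 1e-4
    mi_gross: float = 0.95      # "Mendelian Inheritance Errors" step
    mi_residual: float = 0.99   # "Mendelian Inheritance Errors (<0.01)" step
    duplicate_concordance: float = 0.995


def apply_qc_pipeline(study: GenotypeStudy,
                      thresholds: Optional[QCThresholds] = None
                      ) -> tuple[GenotypeStudy, QCLedger]:
    """Run the ordered marker-exclusion pipeline and record the ledger.

    Step order: sample call rate (samples dropped, not entered in the SNP
    ledger), no-amplify, ambiguous-cluster annotation, monomorphic, HWE,
    gross MI, residual MI (< 0.01 error), low MAF, duplicates, marker call
    rate, two-cluster annotation.
    """
    thresholds = thresholds or QCThresholds()
    # sample pass first
    codes = study.genotypes.codes
    sample_cr = (codes != MISSING).mean(axis=1)
    keep_samples = [s for s, cr in zip(study.sample_ids, sample_cr)
                    if cr >= thresholds.sample_call_rate]
    n_samples_dropped = len(study.sample_ids) - len(keep_samples)
    study = study.subset_samples(keep_samples)

    ledger = QCLedger("array_content", len(study.marker_ids))
    summaries = {s.marker_id: s for s in snp_summary(study, thresholds.hwe_alpha)}
    remaining = list(study.marker_ids)

    def exclude(label: str, condemned: set[str]) -> None:
        nonlocal remaining
        condemned &= set(remaining)
        ledger.add(label, len(condemned))
        remaining = [m for m in remaining if m not in condemned]

    exclude("no_amplify", {m for m in remaining
                           if "no_amplify" in summaries[m].flags or summaries[m].call_rate == 0})
    exclude("ambiguous", {m for m in remaining if "ambiguous" in summaries[m].flags})
    exclude("monomorphic", {m for m in remaining if "monomorphic" in summaries[m].flags})
    exclude("hwe", {m for m in remaining if "hwe_fail" in summaries[m].flags})
    exclude("mi", {m for m in remaining
                   if not math.isnan(summaries[m].mendelian_agreement)
                   and summaries[m].mendelian_agreement < thresholds.mi_gross})
    exclude("mi_residual", {m for m in remaining
                            if not math.isnan(summaries[m].mendelian_agreement)
                            and summaries[m].mendelian_agreement < thresholds.mi_residual})
    exclude("low_maf", {m for m in remaining if summaries[m].maf < thresholds.maf})
    sub = study.subset_markers(remaining)
    _, dup_flagged = detect_duplicates(sub, thresholds.duplicate_concordance)
    exclude("duplicate", set(dup_flagged))
    exclude("low_call", {m for m in remaining
                         if summaries[m].call_rate < thresholds.marker_call_rate})
    exclude("two_cluster", {m for m in remaining if "two_cluster" in summaries[m].flags})

    filtered = study.subset_markers(remaining)
    filtered.metadata["qc_samples_dropped"] = n_samples_dropped
    return filtered, ledger


# ---------------------------------------------------------------------------
# in-silico candidate SNP filter

CANDIDATE_COLUMNS = ["contig_id", "position", "alleles", "read_depth",
                     "minor_allele_reads", "maf_insilico", "snp_quality",
                     "flanking_quality", "probe_type", "repeat_masked",
                     "adt_score", "probe_unique"]


@dataclass
class InsilicoThresholds:
    maf: float = 0.25
    read_depth: int = 10
    minor_allele_reads: int = 2
    snp_quality: float = 25.0
    flanking_quality: float = 25.0
    adt_score: float = 0.7
    proximity_bp: int = 50
    proximity_rule: str = "drop_both"  # or "keep_better"


def insilico_snp_filter(candidates: pd.DataFrame,
                        thresholds: Optional[InsilicoThresholds] = None
                        ) -> tuple[pd.DataFrame, QCLedger]:
    """Sequential candidate-SNP filter with a ledger.

    Order: quality (MAF/depth/minor reads/SNP and flanking quality) ->
    multi-allelic -> Infinium type-I probe chemistry (A/T, C/G) ->
    repeat-masked -> ADT score -> non-unique probe -> flanking-SNP
    proximity (both members of a close pair dropped by default).
    """
    t = thresholds or InsilicoThresholds()
    df = candidates.reset_index(drop=True).copy()
    ledger = QCLedger("candidates", len(df))

    def step(label: str, keep_mask: pd.Series) -> None:
        nonlocal df
        ledger.add(label, int((~keep_mask).sum()))
        df = df[keep_mask].reset_index(drop=True)

    step("quality", (df["maf_insilico"] >= t.maf)
         & (df["read_depth"] >= t.read_depth)
         & (df["minor_allele_reads"] >= t.minor_allele_reads)
         & (df["snp_quality"] >= t.snp_quality)
         & (df["flanking_quality"] >= t.flanking_quality))
    step("multi_allelic", df["alleles"].str.split("/").map(len) <= 2)
    infinium_i = {"A/T", "T/A", "C/G", "G/C"}
    step("infinium_type_i", ~df["alleles"].isin(infinium_i))
    step("repeat_masked", ~df["repeat_masked"].astype(bool))
    step("adt_score", df["adt_score"] >= t.adt_score)
    step("probe_not_unique", df["probe_unique"].astype(bool))

    # proximity: any candidate within `proximity_bp` of another on its contig
    drop = np.zeros(len(df), dtype=bool)
    for _, idx in df.groupby("contig_id").groups.items():
        sub = df.loc[idx].sort_values("position")
        pos = sub["position"].to_numpy()
        close = np.zeros(len(pos), dtype=bool)
        if len(pos) > 1:
            gaps = np.diff(pos)
            near = gaps < t.proximity_bp
            close[:-1] |= near
            close[1:] |= near
        if t.proximity_rule == "keep_better":
            # keep the deeper-read member of each close pair
            order = np.argsort(-sub["read_depth"].to_numpy(), kind="stable")
            kept: list[int] = []
            for k in order:
                if all(abs(pos[k] - pos[o]) >= t.proximity_bp for o in kept):
                    kept.append(k)
            close = np.ones(len(pos), dtype=bool)
            close[kept] = False
        drop[sub.index[close]] = True
    step("flanking_proximity", ~pd.Series(drop, index=df.index))
    return df, ledger


# ---------------------------------------------------------------------------
# parent genotype reconstruction

_TRANSMIT_P = {0: {0: 1.0, 1: 0.0}, 1: {0: 0.5, 1: 0.5}, 2: {0: 0.0, 1: 1.0}}


@dataclass
class ReconstructedGenotype:
    marker_id: str
    ml_genotype: int            # -1 when undefined/incompatible
    log_likelihoods: tuple[float, float, float]
    incompatible: bool
    undefined: bool = False


def reconstruct_parent_genotype(study: GenotypeStudy, unknown_parent: str,
                                known_parent: Optional[str],
                                progeny: Sequence[str]) -> list[ReconstructedGenotype]:
    """Per-locus ML reconstruction of an ungenotyped parent.

    For each candidate parent genotype (0/1/2) the likelihood of the
    observed progeny genotype counts is computed under Mendelian
    transmission with the known parent's genotype fixed (marginalised
    uniformly when it is missing).  Loci where every candidate has zero
    likelihood are flagged incompatible; loci with no genotyped progeny are
    flagged undefined.  Independent per locus — no linkage information.
    """
    gm = study.genotypes
    codes = gm.codes
    kp = codes[gm.sample_row(known_parent)] if known_parent else None
    prog_rows = np.array([gm.sample_row(p) for p in progeny])
    out = []
    for j, mid in enumerate(study.marker_ids):
        obs = codes[prog_rows, j]
        obs = obs[obs != MISSING]
        if obs.size == 0:
            out.append(ReconstructedGenotype(mid, -1, (np.nan,) * 3, False, True))
            continue
        counts = [int((obs == g).sum()) for g in range(3)]
        known = int(kp[j]) if kp is not None else MISSING
        known_states = [known] if known != MISSING else [0, 1, 2]
        lls = []
        for cand in range(3):
            # P(child genotype | cand, known) averaged over unknown known-parent states
            probs = np.zeros(3)
            for ks in known_states:
                for a in range(2):
                    for b in range(2):
                        probs[a + b] += (_TRANSMIT_P[cand][a] * _TRANSMIT_P[ks][b]
                                         / len(known_states))
            with np.errstate(divide="ignore"):
                ll = sum(c * np.log(probs[g]) if c > 0 else 0.0
                         for g, c in enumerate(counts))
            lls.append(float(ll) if np.isfinite(ll) else -np.inf)
        if all(not np.isfinite(v) for v in lls):
            out.append(ReconstructedGenotype(mid, -1, tuple(lls), True))
        else:
            out.append(ReconstructedGenotype(mid, int(np.argmax(lls)), tuple(lls), False))
    return out
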