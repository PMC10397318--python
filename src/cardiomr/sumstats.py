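"""GWAS summary statistics: container, TSV I/O, fixed-effects meta-analysis,
genomic-control correction, quality filters, pruning, loci, replication flags,
and meta-subtraction.

The unit of exchange is :class:`SummaryStats`, a thin wrapper around a pandas
DataFrame with the columns ``SNP CHR POS EA OA EAF BETA SE P N INFO`` (the
dialect emitted by most meta-analysis tools).  All operations return new
objects; nothing mutates its input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .statsutil import p_from_z

log = logging.getLogger(__name__)

COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N", "INFO"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement(allele: str) -> str:
    """Reverse-strand complement of an allele string (e.g. 'AG' -> 'TC')."""
    return "".join(_COMPLEMENT.get(b, "N") for b in allele)


def is_palindromic(ea: str, oa: str) -> bool:
    """A/T or C/G pairs: indistinguishable across strands."""
    return complement(ea) == oa


@dataclass
class SummaryStats:
    """Per-variant association table plus provenance metadata.

    ``table`` holds one row per variant; variant ids are unique and rows are
    sorted by (CHR, POS).  ``gc_intercept_applied`` records any genomic-control
    inflation factor already multiplied into the standard errors.
    """

    table: pd.DataFrame
    provenance: str = ""
    gc_intercept_applied: float | None = None

    def __post_init__(self):
        df = self.table.copy()
        for col in COLUMNS:
            if col not in df.columns:
                if col == "INFO":
                    df["INFO"] = 1.0
                else:
                    raise ValueError(f"missing required column {col}")
        extras = [c for c in df.columns if c not in COLUMNS]
        df = df[COLUMNS + extras]
        if df["SNP"].duplicated().any():
            dup = df.loc[df["SNP"].duplicated(), "SNP"].iloc[0]
            raise ValueError(f"duplicate variant id {dup!r}")
        if (df["SE"] <= 0).any():
            raise ValueError("all SE must be > 0")
        eaf = df["EAF"].to_numpy(float)
        if np.any((eaf <= 0) | (eaf >= 1)):
            raise ValueError("EAF must lie in (0, 1)")
        if (df["EA"] == df["OA"]).any():
            raise ValueError("effect and other allele must differ")
        df = df.sort_values(["CHR", "POS"], kind="mergesort").reset_index(drop=True)
        self.table = df

    def __len__(self):
        return len(self.table)

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("SNP")

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def read_tsv(cls, path, provenance: str | None = None) -> "SummaryStats":
        df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str, "EA": str, "OA": str})
        ss = cls(df, provenance=provenance or str(path))
        # sanity: reported P should agree with |beta/se| (within 10% relative),
        # the same consistency check applied to incoming cohort files
        t = ss.table
        expect = p_from_z(t["BETA"].to_numpy(float) / t["SE"].to_numpy(float))
        rep = t["P"].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            bad = (expect > 0) & (np.abs(rep - expect) > 0.10 * expect)
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} variants have P inconsistent with beta/SE "
                f"(first: {t.loc[np.flatnonzero(bad)[0], 'SNP']})"
            )
        return ss

    def write_tsv(self, path) -> None:
        """Write the standard tab-separated dialect with stable %.6g formatting."""
        df = self.table.copy()
        for col in ["EAF", "BETA", "SE", "P", "INFO"]:
            df[col] = df[col].map(lambda v: f"{v:.6g}")
        df.to_csv(path, sep="\t", index=False)


@dataclass
class LDTable:
    """Sparse pairwise LD (r²) lookup with implied symmetry; self-pairs are 1."""

    pairs: pd.DataFrame  # columns SNP_A, SNP_B, R2

    def __post_init__(self):
        df = self.pairs
        r2 = df["R2"].to_numpy(float)
        if np.any((r2 < 0) | (r2 > 1)):
            raise ValueError("r2 must lie in [0, 1]")
        self._lookup = {}
        for a, b, r in zip(df["SNP_A"], df["SNP_B"], r2):
            self._lookup[(a, b)] = r
            self._lookup[(b, a)] = r

    def r2(self, a: str, b: str) -> float:
        """r² between two variants; 1 for self-pairs, 0 when unrecorded."""
        if a == b:
            return 1.0
        return self._lookup.get((a, b), 0.0)

    def proxies(self, snp: str, r2_min: float) -> list[tuple[str, float]]:
        """Variants in LD with ``snp`` above ``r2_min``, best first."""
        out = [(b, r) for (a, b), r in self._lookup.items() if a == snp and r > r2_min and b != snp]
        return sorted(out, key=lambda t: (-t[1], t[0]))

    @classmethod
    def read_tsv(cls, path) -> "LDTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"SNP_A": str, "SNP_B": str}))

    def write_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# allele alignment used by the meta stage


def _align_to(ref_ea, ref_oa, ref_eaf, ea, oa, eaf, freq_gate=0.08):
    """Orient one study's record to a reference allele pair.

    Returns +1 (aligned), -1 (flip beta and EAF) or None (irreconcilable).
    Palindromic pairs are resolved by allele frequency only when both sides
    are informative (|EAF - 0.5| > freq_gate); otherwise dropped as ambiguous.
    """
    if is_palindromic(ref_ea, ref_oa):
        if {ea, oa} != {ref_ea, ref_oa}:
            return None
        if abs(ref_eaf - 0.5) <= freq_gate or abs(eaf - 0.5) <= freq_gate:
            return None
        # orient so that minor/major status of the effect allele matches
        same = (ref_eaf - 0.5) * (eaf - 0.5) > 0
        return 1 if (ea == ref_ea) == same else -1
    if (ea, oa) == (ref_ea, ref_oa):
        return 1
    if (ea, oa) == (ref_oa, ref_ea):
        return -1
    cea, coa = complement(ea), complement(oa)
    if (cea, coa) == (ref_ea, ref_oa):
        return 1
    if (cea, coa) == (ref_oa, ref_ea):
        return -1
    return None


def ivw_meta(stats_list: list[SummaryStats], provenance: str = "ivw_meta") -> SummaryStats:
    """Fixed-effects inverse-variance-weighted meta-analysis (METAL scheme).

    Per shared variant: weights w_i = 1/se_i², pooled beta = Σw·b/Σw, pooled
    se = 1/√Σw, P from the pooled Z, N summed, EAF the N-weighted mean.
    Variants present in a single input are carried through with INFO etc.
    untouched.  Studies whose alleles cannot be reconciled at a variant are
    dropped from that variant with a logged reason.
    """
    if len(stats_list) < 2:
        if len(stats_list) == 1:
            return replace(stats_list[0], provenance=provenance)
        raise ValueError("need at least one input")
    frames = [s.indexed() for s in stats_list]
    all_ids = frames[0].index
    for f in frames[1:]:
        all_ids = all_ids.union(f.index)

    rows = []
    for snp in all_ids:
        present = [f.loc[snp] for f in frames if snp in f.index]
        ref = present[0]
        aligned = [ref]
        for rec in present[1:]:
            sign = _align_to(ref["EA"], ref["OA"], ref["EAF"], rec["EA"], rec["OA"], rec["EAF"])
            if sign is None:
                log.info("variant %s: irreconcilable alleles in one study; study dropped", snp)
                continue
            r = rec.copy()
            if sign < 0:
                r["BETA"] = -r["BETA"]
                r["EAF"] = 1.0 - r["EAF"]
            aligned.append(r)
        b = np.array([r["BETA"] for r in aligned], float)
        se = np.array([r["SE"] for r in aligned], float)
        n = np.array([r["N"] for r in aligned], float)
        eaf = np.array([r["EAF"] for r in aligned], float)
        info = np.array([r["INFO"] for r in aligned], float)
        w = 1.0 / se**2
        beta = float((w * b).sum() / w.sum())
        pooled_se = float(1.0 / np.sqrt(w.sum()))
        rows.append(
            dict(
                SNP=snp,
                CHR=ref["CHR"],
                POS=ref["POS"],
                EA=ref["EA"],
                OA=ref["OA"],
                EAF=float((n * eaf).sum() / n.sum()),
                BETA=beta,
                SE=pooled_se,
                P=p_from_z(beta / pooled_se),
                N=float(n.sum()),
                INFO=float((n * info).sum() / n.sum()),
                N_STUDIES=len(aligned),
            )
        )
    df = pd.DataFrame(rows)
    df["SINGLE_STUDY"] = df.pop("N_STUDIES") == 1
    return SummaryStats(df, provenance=provenance)


def genomic_control_correct(stats: SummaryStats, intercept: float) -> SummaryStats:
    """Inflate standard errors by √intercept (LD-score-regression intercept or
    lambda-GC) and recompute P from beta/se'."""
    if intercept <= 0:
        raise ValueError("genomic-control intercept must be positive")
    if intercept < 1:
        log.warning("genomic-control intercept %.4f < 1 deflates standard errors", intercept)
    df = stats.table.copy()
    df["SE"] = df["SE"] * np.sqrt(intercept)
    df["P"] = p_from_z(df["BETA"].to_numpy(float) / df["SE"].to_numpy(float))
    return SummaryStats(df, provenance=stats.provenance, gc_intercept_applied=intercept)


def neff_filter(stats: SummaryStats, info_min: float = 0.3, neff_min: float = 25.0) -> SummaryStats:
    """Drop poorly informative imputed variants.

    Retains records with INFO >= info_min and effective sample size
    N·Info·2·MAF·(1-MAF) >= neff_min, with MAF = min(EAF, 1-EAF).
    """
    df = stats.table
    eaf = df["EAF"].to_numpy(float)
    maf = np.minimum(eaf, 1 - eaf)
    info = df["INFO"].to_numpy(float)
    neff = df["N"].to_numpy(float) * info * 2 * maf * (1 - maf)
    bad_info = info < info_min
    bad_neff = neff < neff_min
    keep = ~(bad_info | bad_neff)
    log.info(
        "neff_filter: %d excluded by INFO < %g, %d by N_eff < %g (of %d)",
        int(bad_info.sum()), info_min, int((bad_neff & ~bad_info).sum()), neff_min, len(df),
    )
    return SummaryStats(df[keep].reset_index(drop=True), provenance=stats.provenance,
                        gc_intercept_applied=stats.gc_intercept_applied)


def prune_independent(
    stats: SummaryStats,
    ld: LDTable,
    p_threshold: float = 1e-8,
    r2_max: float = 0.005,
    window_bp: float = 5e6,
) -> list[str]:
    """Greedy LD pruning to an independent genome-wide-significant set.

    Candidates with P < p_threshold are visited by ascending P (ties by
    chromosome then position); a candidate is rejected when r² >= r2_max with
    an already-selected variant within ``window_bp`` on the same chromosome.
    Missing LD pairs are treated as r² = 0.
    """
    df = stats.table
    cand = df[df["P"] < p_threshold].sort_values(["P", "CHR", "POS"], kind="mergesort")
    selected: list[tuple[str, str, int]] = []
    for _, row in cand.iterrows():
        ok = True
        for sid, schr, spos in selected:
            if schr == row["CHR"] and abs(spos - row["POS"]) <= window_bp:
                if ld.r2(sid, row["SNP"]) >= r2_max:
                    ok = False
                    break
        if ok:
            selected.append((row["SNP"], row["CHR"], int(row["POS"])))
    return [s[0] for s in selected]


def define_loci(independent: list[str], stats: SummaryStats, flank_bp: float = 1e6) -> pd.DataFrame:
    """Closed-interval loci of ±flank_bp around each independent variant;
    overlapping spans are merged and the most significant variant in the span
    becomes the locus top variant.

    Returns a DataFrame with columns CHR, START, END, TOP_SNP, TOP_P.
    """
    idx = stats.indexed()
    missing = [s for s in independent if s not in idx.index]
    if missing:
        raise ValueError(f"independent variants absent from stats: {missing[:3]}")
    spans = []
    for snp in independent:
        row = idx.loc[snp]
        spans.append((row["CHR"], row["POS"] - flank_bp, row["POS"] + flank_bp))
    spans.sort(key=lambda t: (str(t[0]), t[1]))
    merged = []
    for chrom, lo, hi in spans:
        if merged and merged[-1][0] == chrom and lo <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], hi)
        else:
            merged.append([chrom, lo, hi])
    t = stats.table
    out = []
    for chrom, lo, hi in merged:
        inside = t[(t["CHR"] == chrom) & (t["POS"] >= lo) & (t["POS"] <= hi)]
        top = inside.loc[inside["P"].idxmin()]
        out.append(dict(CHR=chrom, START=lo, END=hi, TOP_SNP=top["SNP"], TOP_P=top["P"]))
    return pd.DataFrame(out)


def replication_flags(
    meta: SummaryStats,
    cohort_a: SummaryStats,
    cohort_b: SummaryStats,
    known_loci: pd.DataFrame | None = None,
    p_meta: float = 1e-8,
    p_support: float = 0.01,
    novel_distance_bp: float = 1e6,
) -> pd.DataFrame:
    """One-stage replication flags per variant.

    A signal is ``replicated`` when all four hold: meta P < p_meta; support
    (P < p_support) in each cohort alone; concordant direction between the
    cohorts.  ``novel`` flags variants farther than ``novel_distance_bp`` from
    every known locus boundary.
    """
    a, b = cohort_a.indexed(), cohort_b.indexed()
    rows = []
    for _, m in meta.table.iterrows():
        snp = m["SNP"]
        rec = dict(SNP=snp, meta_significant=bool(m["P"] < p_meta))
        if snp in a.index and snp in b.index:
            ra, rb = a.loc[snp], b.loc[snp]
            sa = _align_to(m["EA"], m["OA"], m["EAF"], ra["EA"], ra["OA"], ra["EAF"]) or 1
            sb = _align_to(m["EA"], m["OA"], m["EAF"], rb["EA"], rb["OA"], rb["EAF"]) or 1
            rec["support_cohort_a"] = bool(ra["P"] < p_support)
            rec["support_cohort_b"] = bool(rb["P"] < p_support)
            rec["concordant_direction"] = bool((sa * ra["BETA"]) * (sb * rb["BETA"]) > 0)
            rec["reason"] = ""
        else:
            rec["support_cohort_a"] = rec["support_cohort_b"] = False
            rec["concordant_direction"] = False
            rec["reason"] = "absent from a cohort table"
        rec["replicated"] = (
            rec["meta_significant"]
            and rec["support_cohort_a"]
            and rec["support_cohort_b"]
            and rec["concordant_direction"]
        )
        novel = True
        if known_loci is not None and len(known_loci):
            same = known_loci[known_loci["CHR"] == m["CHR"]]
            for _, loc in same.iterrows():
                dist = max(loc["START"] - m["POS"], m["POS"] - loc["END"], 0)
                if dist <= novel_distance_bp:
                    novel = False
                    break
        rec["novel"] = novel
        rows.append(rec)
    return pd.DataFrame(rows)


def meta_subtract(meta: SummaryStats, cohort: SummaryStats) -> SummaryStats:
    """Remove one cohort's contribution from an IVW meta-analysis.

    Inverse of the pooling algebra: w_r = w_m - w_c, beta_r = (w_m·b_m -
    w_c·b_c)/w_r, se_r = 1/√w_r, N_r = N_m - N_c.  Variants where the cohort
    carries at least the meta weight are dropped with a logged reason (the
    inputs are then inconsistent with the cohort being a subset of the meta).
    """
    c = cohort.indexed()
    rows = []
    for _, m in meta.table.iterrows():
        snp = m["SNP"]
        if snp not in c.index:
            rows.append(dict(m))
            continue
        rec = c.loc[snp]
        sign = _align_to(m["EA"], m["OA"], m["EAF"], rec["EA"], rec["OA"], rec["EAF"])
        if sign is None:
            log.info("meta_subtract: variant %s alleles irreconcilable; dropped", snp)
            continue
        b_c = sign * rec["BETA"]
        w_m, w_c = 1.0 / m["SE"] ** 2, 1.0 / rec["SE"] ** 2
        if w_c >= w_m:
            log.info("meta_subtract: variant %s cohort weight >= meta weight; dropped", snp)
            continue
        w_r = w_m - w_c
        beta = (w_m * m["BETA"] - w_c * b_c) / w_r
        se = 1.0 / np.sqrt(w_r)
        row = dict(m)
        row.update(BETA=beta, SE=se, P=p_from_z(beta / se), N=m["N"] - rec["N"])
        rows.append(row)
    if not rows:
        raise ValueError("meta_subtract removed every variant (cohort is not a strict subset)")
    df = pd.DataFrame(rows)
    df = df[[c for c in df.columns if c in COLUMNS]]
    return SummaryStats(df, provenance=f"{meta.provenance} minus {cohort.provenance}")
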