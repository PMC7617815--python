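"""Codon substitution-rate analysis for X/Y/outgroup gametolog triplets.

Implements a Nei–Gojobori (1986) pairwise estimator with Jukes–Cantor
multiple-hit correction, an additive three-taxon branch decomposition on the
fixed ((X,Y),outgroup) topology, and region-level aggregation of dS, dN and
omega = dN/dS, mirroring the per-region summary tables of sex-chromosome
divergence studies.

The pairwise estimator counts synonymous and nonsynonymous sites per codon
(stop-creating changes counted as nonsynonymous, so S + N = 3 per codon) and
averages difference counts over all minimal mutational pathways between
differing codons, excluding pathways through stop codons. Proportions are
corrected with d = -(3/4)·ln(1 - (4/3)p), which is accurate at the low
divergences (dS <~ 0.15) this package targets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from ._codon import (
    CODON_TO_AA,
    STOP_CODONS,
    codon_site_counts,
    pathway_diff_counts,
    split_codons,
)

__all__ = [
    "SaturationError",
    "GametologTriplet",
    "DivergenceEstimate",
    "jukes_cantor",
    "codon_align",
    "ng86_pairwise",
    "branch_decompose",
    "aggregate_region",
    "paired_omega_test",
]


class SaturationError(ValueError):
    """Raised when a difference proportion is outside the Jukes–Cantor domain."""


@dataclass
class GametologTriplet:
    """Codon-aligned X/Y/outgroup coding sequences for one gene.

    Aligned sequences have equal length divisible by 3 and may contain '-'
    (gap) and 'N'; any codon that is not a clean sense codon in a compared
    pair is masked from counting.
    """

    gene_id: str
    region: str | None = None
    x_cds: str | None = None
    y_cds: str | None = None
    og_cds: str | None = None

    @property
    def n_codons(self) -> int:
        for seq in (self.x_cds, self.y_cds, self.og_cds):
            if seq is not None:
                return len(seq) // 3
        return 0


@dataclass
class DivergenceEstimate:
    gene_id: str
    label: str  # XY, X_OG, Y_OG, branch_X, branch_Y, branch_OG
    dS: float | None
    dN: float | None
    omega: float | None
    S_sites: float
    N_sites: float
    n_codons: int = 0
    pS: float | None = None
    pN: float | None = None
    saturated: bool = False


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor correction d = -(3/4)·ln(1 - (4/3)p).

    Raises SaturationError for p >= 3/4, where the correction is undefined.
    """
    if p < 0:
        raise ValueError(f"proportion must be >= 0, got {p}")
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} >= 3/4: distance saturated")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# codon-aware alignment


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def _translate(seq: str) -> str | None:
    """Translate an in-frame CDS; N-containing codons become 'X'.

    Returns None if the translation contains an internal stop (terminal stop
    codons are trimmed before translation by the caller).
    """
    aas = []
    for codon in split_codons(seq):
        if codon in STOP_CODONS:
            return None
        aa = CODON_TO_AA.get(codon)
        aas.append(aa if aa is not None else "X")
    return "".join(aas)


def _trim_terminal_stop(seq: str) -> str:
    if len(seq) >= 3 and seq[-3:] in STOP_CODONS:
        return seq[:-3]
    return seq


def _pairwise_codon_align(ref_cds: str, other_cds: str) -> tuple[str, str]:
    """Globally align two CDS at the peptide level and back-thread to codons."""
    pep_a = _translate(ref_cds)
    pep_b = _translate(other_cds)
    if pep_a is None or pep_b is None:
        raise ValueError("internal stop codon in reading frame")
    aln = _ALIGNER.align(pep_a, pep_b)[0]
    a_idx = b_idx = 0
    out_a, out_b = [], []
    for col_a, col_b in zip(aln[0], aln[1]):
        if col_a == "-":
            out_a.append("---")
        else:
            out_a.append(ref_cds[3 * a_idx : 3 * a_idx + 3])
            a_idx += 1
        if col_b == "-":
            out_b.append("---")
        else:
            out_b.append(other_cds[3 * b_idx : 3 * b_idx + 3])
            b_idx += 1
    return "".join(out_a), "".join(out_b)


def codon_align(
    x_cds: str,
    y_cds: str | None,
    og_cds: str | None,
    gene_id: str = "gene",
    region: str | None = None,
) -> GametologTriplet:
    """Build a codon alignment of the X CDS with its Y and outgroup homologs.

    Peptide-guided: each non-X sequence is globally aligned to the X peptide
    (Needleman–Wunsch, BLOSUM62, affine gaps) and the alignment is
    back-threaded to codons; positions where the X sequence would be gapped
    relative to a partner are dropped so all sequences share X codon
    coordinates. Sequences that are entirely N are treated as missing.
    """
    x_cds = _trim_terminal_stop(x_cds.upper())
    n_codons = len(x_cds) // 3
    aligned: dict[str, str | None] = {"y": None, "og": None}
    for key, seq in (("y", y_cds), ("og", og_cds)):
        if seq is None:
            continue
        seq = _trim_terminal_stop(seq.upper())
        if not seq or set(seq) <= {"N", "-"}:
            continue
        try:
            a_x, a_o = _pairwise_codon_align(x_cds, seq)
        except ValueError:
            warnings.warn(f"{gene_id}: internal stop in {key} sequence; skipped")
            continue
        # project onto X codon coordinates: drop columns gapped in X
        codons_x = split_codons(a_x)
        codons_o = split_codons(a_o)
        proj = [co for cx, co in zip(codons_x, codons_o) if cx != "---"]
        assert len(proj) == n_codons
        aligned[key] = "".join(proj)
    return GametologTriplet(
        gene_id=gene_id,
        region=region,
        x_cds=x_cds,
        y_cds=aligned["y"],
        og_cds=aligned["og"],
    )


# ---------------------------------------------------------------------------
# NG86 pairwise estimation


def _countable(codon: str) -> bool:
    return codon in CODON_TO_AA and codon not in STOP_CODONS


def ng86_pairwise(
    seq_a: str,
    seq_b: str,
    gene_id: str = "gene",
    label: str = "pair",
) -> DivergenceEstimate:
    """Nei–Gojobori (1986) dS/dN between two aligned in-frame sequences.

    Codons containing gaps, N or stops in either sequence are masked. When a
    difference proportion reaches the Jukes–Cantor saturation bound the
    corresponding distance is reported as None with ``saturated`` set.
    """
    codons_a = split_codons(seq_a.upper())
    codons_b = split_codons(seq_b.upper())
    if len(codons_a) != len(codons_b):
        raise ValueError("aligned sequences differ in length")
    S = N = 0.0
    Sd = Nd = 0.0
    n_countable = 0
    for ca, cb in zip(codons_a, codons_b):
        if not (_countable(ca) and _countable(cb)):
            continue
        n_countable += 1
        sa, na = codon_site_counts(ca)
        sb, nb = codon_site_counts(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = pathway_diff_counts(ca, cb)
        Sd += sd
        Nd += nd
    if n_countable == 0:
        raise ValueError(f"{gene_id}: no countable codons in {label}")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = dN = None
    saturated = False
    try:
        dS = jukes_cantor(pS)
    except SaturationError:
        saturated = True
    try:
        dN = jukes_cantor(pN)
    except SaturationError:
        saturated = True
    omega = None
    if dS is not None and dN is not None and dS > 0:
        omega = dN / dS
    return DivergenceEstimate(
        gene_id=gene_id,
        label=label,
        dS=dS,
        dN=dN,
        omega=omega,
        S_sites=S,
        N_sites=N,
        n_codons=n_countable,
        pS=pS,
        pN=pN,
        saturated=saturated,
    )


def triplet_pairwise(triplet: GametologTriplet) -> dict[str, DivergenceEstimate | None]:
    """All defined pairwise NG86 estimates for a triplet (XY, X_OG, Y_OG)."""
    out: dict[str, DivergenceEstimate | None] = {"XY": None, "X_OG": None, "Y_OG": None}
    pairs = {
        "XY": (triplet.x_cds, triplet.y_cds),
        "X_OG": (triplet.x_cds, triplet.og_cds),
        "Y_OG": (triplet.y_cds, triplet.og_cds),
    }
    for label, (a, b) in pairs.items():
        if a is None or b is None:
            continue
        try:
            out[label] = ng86_pairwise(a, b, gene_id=triplet.gene_id, label=label)
        except ValueError:
            out[label] = None
    return out


# ---------------------------------------------------------------------------
# branch decomposition


def _decompose(d_xy, d_x_og, d_y_og):
    bx = max(0.0, (d_xy + d_x_og - d_y_og) / 2.0)
    by = max(0.0, (d_xy + d_y_og - d_x_og) / 2.0)
    bog = max(0.0, (d_x_og + d_y_og - d_xy) / 2.0)
    return bx, by, bog


def branch_decompose(
    est_xy: DivergenceEstimate | None,
    est_x_og: DivergenceEstimate | None,
    est_y_og: DivergenceEstimate | None,
) -> dict[str, DivergenceEstimate] | None:
    """Additive decomposition of pairwise distances into per-branch dS and dN.

    On the unrooted three-taxon tree, branch_X = (d_XY + d_X:OG - d_Y:OG)/2
    and cyclically; negative raw values are clamped to 0. Each class (dS, dN)
    is decomposed separately and omega = dN_branch/dS_branch where
    dS_branch > 0. Returns None if any pairwise estimate (or its class) is
    missing.
    """
    ests = (est_xy, est_x_og, est_y_og)
    if any(e is None or e.dS is None or e.dN is None for e in ests):
        return None
    ds = _decompose(est_xy.dS, est_x_og.dS, est_y_og.dS)
    dn = _decompose(est_xy.dN, est_x_og.dN, est_y_og.dN)
    gene_id = est_xy.gene_id
    out = {}
    for label, dS_b, dN_b in zip(("branch_X", "branch_Y", "branch_OG"), ds, dn):
        omega = dN_b / dS_b if dS_b > 0 else None
        out[label] = DivergenceEstimate(
            gene_id=gene_id,
            label=label,
            dS=dS_b,
            dN=dN_b,
            omega=omega,
            S_sites=est_xy.S_sites,
            N_sites=est_xy.N_sites,
            n_codons=est_xy.n_codons,
        )
    return out


def estimates_table(triplets: list[GametologTriplet]) -> pd.DataFrame:
    """Per-gene pairwise + branch estimates for a set of aligned triplets.

    Returns a tidy frame with one row per (gene, label); labels are the three
    pairs and, where all pairs are defined, the three branches.
    """
    rows = []
    for trip in triplets:
        pairs = triplet_pairwise(trip)
        branches = branch_decompose(pairs["XY"], pairs["X_OG"], pairs["Y_OG"])
        for est in list(pairs.values()) + list((branches or {}).values()):
            if est is None:
                continue
            rows.append(
                {
                    "gene_id": est.gene_id,
                    "region": trip.region,
                    "label": est.label,
                    "dS": est.dS,
                    "dN": est.dN,
                    "omega": est.omega,
                    "S_sites": est.S_sites,
                    "N_sites": est.N_sites,
                    "n_codons": est.n_codons,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "region",
            "label",
            "dS",
            "dN",
            "omega",
            "S_sites",
            "N_sites",
            "n_codons",
        ],
    )


# ---------------------------------------------------------------------------
# region aggregation and tests

_SUMMARY_STATS = {
    "dS_X_OG": ("X_OG", "dS"),
    "dS_XY": ("XY", "dS"),
    "omega_X": ("branch_X", "omega"),
    "omega_Y": ("branch_Y", "omega"),
    "omega_X_OG": ("X_OG", "omega"),
}


def aggregate_region(estimates: pd.DataFrame, region_labels: dict[str, str] | None = None) -> pd.DataFrame:
    """Region-level means ± standard errors of the per-gene estimates.

    ``estimates`` is the tidy frame from :func:`estimates_table`;
    ``region_labels`` optionally overrides the region column (gene_id → region,
    e.g. derived from a Marey-map segmentation). For each statistic the mean,
    SE = sd/sqrt(n) and per-statistic n (genes with a defined value) are
    reported; a pooled value (ratio of summed dN to summed dS across genes,
    weight-stable for noisy per-gene ratios) is added for the omega statistics.
    """
    df = estimates.copy()
    if region_labels is not None:
        df["region"] = df["gene_id"].map(region_labels)
    df = df[df["region"].notna()]
    rows = []
    for region, sub in df.groupby("region"):
        n_genes = sub["gene_id"].nunique()
        if n_genes == 0:
            warnings.warn(f"region {region}: no genes, omitted")
            continue
        row: dict[str, object] = {
            "region": region,
            "n_genes": n_genes,
            "n_codons": int(
                sub[sub["label"] == "XY"]["n_codons"].sum()
                or sub[sub["label"] == "X_OG"]["n_codons"].sum()
            ),
        }
        for stat, (label, col) in _SUMMARY_STATS.items():
            vals = sub.loc[sub["label"] == label, col].dropna().to_numpy(float)
            n = len(vals)
            row[f"{stat}_mean"] = float(np.mean(vals)) if n else None
            row[f"{stat}_se"] = (
                float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else None
            )
            row[f"{stat}_n"] = n
        for stat, label in (("omega_X", "branch_X"), ("omega_Y", "branch_Y")):
            b = sub[sub["label"] == label]
            ds_sum = b["dS"].sum()
            row[f"{stat}_pooled"] = float(b["dN"].sum() / ds_sum) if ds_sum > 0 else None
        rows.append(row)
    return pd.DataFrame(rows)


def paired_omega_test(omega_x, omega_y) -> dict[str, float]:
    """Two-sided paired t-test of per-gene omega_Y − omega_X.

    Pairs with a missing value are dropped; requires >= 3 complete pairs.
    Identical pairs (zero variance of differences) are reported as t = 0,
    p = 1.
    """
    from scipy import stats

    x = np.asarray(omega_x, dtype=float)
    y = np.asarray(omega_y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"paired test requires >= 3 complete pairs, got {n}")
    diffs = y - x
    if np.allclose(diffs.std(ddof=1), 0.0):
        t_stat, p = (0.0, 1.0) if np.allclose(diffs, 0.0) else (math.inf, 0.0)
    else:
        t_stat, p = stats.ttest_rel(y, x)
    return {"t": float(t_stat), "p": float(p), "n": n}
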