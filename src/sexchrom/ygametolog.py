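"""Pedigree-segregation reconstruction of Y-linked gametologs.

A Y-diagnostic SNP is a variant allele transmitted from the father to every
son and to no daughter. Sites are classified from per-individual allele
depths; read pairs are partitioned into Y and X bins by the diagnostic
alleles they carry; the Y-binned pileup over each gene's CDS yields a
majority-rule Y consensus sequence. Against simulated truth, site-level
precision/recall and per-base consensus accuracy are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "classify_sites",
    "partition_reads",
    "build_consensus",
    "consensus_from_cross",
    "validate_against_truth",
    "YConsensus",
]

BASES = "ACGT"


@dataclass
class YConsensus:
    gene_id: str
    sequence: str  # 'N' where depth or majority fails
    depth: np.ndarray
    fraction_called: float


def _carries(depths: np.ndarray, base_idx: int, min_reads: int = 2, min_frac: float = 0.05) -> bool:
    """Whether an individual's depths support carrying the given allele."""
    total = depths.sum()
    if total == 0:
        return False
    d = depths[base_idx]
    return d >= min_reads and d / total >= min_frac


def _classify_one(
    counts: dict[str, np.ndarray],
    roles: pd.DataFrame,
    min_depth: int,
    min_informative_fraction: float,
    rna_son_dropout_tolerance: float,
    maternal_impurity: float,
):
    """Classify one site in one family. Returns dict of result fields."""
    out = {"x_allele": None, "y_allele": None, "n_sons_support": 0,
           "n_sons_informative": 0, "n_daughters_checked": 0}

    def depths(sid):
        return counts.get(sid, np.zeros(4, dtype=np.int64))

    father_id = roles.loc[roles["role"] == "father", "sample_id"].iloc[0]
    mother_id = roles.loc[roles["role"] == "mother", "sample_id"].iloc[0]
    md = depths(mother_id)
    m_total = md.sum()
    if m_total < min_depth:
        return {**out, "status": "rejected", "reject_reason": "mother_low_depth"}
    a_idx = int(md.argmax())
    if (m_total - md[a_idx]) / m_total >= maternal_impurity:
        return {**out, "status": "rejected", "reject_reason": "mother_heterozygous"}
    out["x_allele"] = BASES[a_idx]

    fd = depths(father_id)
    if fd.sum() < min_depth:
        return {**out, "status": "rejected", "reject_reason": "father_low_depth"}
    b_candidates = [
        i for i in np.argsort(fd)[::-1]
        if i != a_idx and _carries(fd, int(i), min_frac=0.15)
    ]
    if not b_candidates:
        return {**out, "status": "rejected", "reject_reason": "father_no_second_allele"}
    if not _carries(fd, a_idx, min_frac=0.15):
        return {**out, "status": "rejected", "reject_reason": "father_lacks_maternal_allele"}
    b_idx = int(b_candidates[0])
    out["y_allele"] = BASES[b_idx]
    if _carries(md, b_idx, min_frac=maternal_impurity):
        return {**out, "status": "rejected", "reject_reason": "mother_carries_y"}

    progeny = roles[roles["role"] == "offspring"]
    n_informative = 0
    sons_support = sons_informative = 0
    rna_sons_support = rna_sons_informative = 0
    daughters_checked = 0
    for _, p in progeny.iterrows():
        d = depths(p["sample_id"])
        informative = d.sum() >= min_depth
        if informative:
            n_informative += 1
        if p["sex"] == "M":
            if not informative:
                continue
            sons_informative += 1
            has_b = _carries(d, b_idx)
            if p["datatype"] == "genomic":
                if not has_b:
                    out.update(n_sons_informative=sons_informative,
                               n_daughters_checked=daughters_checked)
                    return {**out, "status": "rejected", "reject_reason": "son_missing_y"}
                sons_support += 1
            else:
                rna_sons_informative += 1
                if has_b:
                    rna_sons_support += 1
                    sons_support += 1
        else:
            if not informative:
                continue
            daughters_checked += 1
            if _carries(d, b_idx):
                out.update(n_sons_support=sons_support, n_sons_informative=sons_informative,
                           n_daughters_checked=daughters_checked)
                return {**out, "status": "rejected", "reject_reason": "daughter_carries_y"}
    out.update(n_sons_support=sons_support, n_sons_informative=sons_informative,
               n_daughters_checked=daughters_checked)
    if sons_informative == 0:
        return {**out, "status": "rejected", "reject_reason": "no_informative_sons"}
    if rna_sons_informative > 0:
        if rna_sons_support < (1.0 - rna_son_dropout_tolerance) * rna_sons_informative:
            return {**out, "status": "rejected", "reject_reason": "rna_son_dropout"}
    if len(progeny) and n_informative / len(progeny) < min_informative_fraction:
        return {**out, "status": "rejected", "reject_reason": "insufficient_informative"}
    return {**out, "status": "Y_linked", "reject_reason": None}


def classify_sites(
    observations: pd.DataFrame,
    pedigree: pd.DataFrame,
    min_depth: int = 5,
    min_informative_fraction: float = 0.8,
    rna_son_dropout_tolerance: float = 0.2,
    maternal_impurity: float = 0.1,
) -> pd.DataFrame:
    """Classify candidate sites as Y-linked or rejected from cross segregation.

    A site is Y_linked iff, in every family where it is informative: the
    mother is homozygous (alternate allele fraction below
    ``maternal_impurity``); the father carries a second allele B absent from
    the mother; every genome-sequenced son with depth >= ``min_depth``
    carries B; at least (1 − ``rna_son_dropout_tolerance``) of informative
    transcriptome-sequenced sons carry B (Y copies may be silenced in
    expression data); no daughter of any data type with adequate depth
    carries B; and at least ``min_informative_fraction`` of progeny are
    informative. Sites with no coverage anywhere are skipped.
    """
    ped = pedigree
    if "family" not in ped.columns:
        ped = ped.assign(family="fam1")
    required = {"chrom", "pos", "sample_id", "A", "C", "G", "T"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observations lack columns {sorted(missing)}")
    fam_roles = {fam: sub for fam, sub in ped.groupby("family")}
    for fam, sub in fam_roles.items():
        if (sub["role"] == "father").sum() != 1 or (sub["role"] == "mother").sum() != 1:
            raise ValueError(f"family {fam} must have exactly one father and one mother")
    sample_family = ped.set_index("sample_id")["family"].to_dict()

    rows = []
    base_cols = list(BASES)
    for (chrom, pos), site in observations.groupby(["chrom", "pos"], sort=True):
        depth_map = {
            r.sample_id: np.array([getattr(r, b) for b in base_cols], dtype=np.int64)
            for r in site.itertuples()
        }
        if sum(d.sum() for d in depth_map.values()) == 0:
            logger.debug("site %s:%s has zero depth everywhere; skipped", chrom, pos)
            continue
        fam_results = []
        for fam, roles in fam_roles.items():
            fam_counts = {s: d for s, d in depth_map.items() if sample_family.get(s) == fam}
            if not fam_counts:
                continue
            fam_results.append(
                _classify_one(fam_counts, roles, min_depth, min_informative_fraction,
                              rna_son_dropout_tolerance, maternal_impurity)
            )
        if not fam_results:
            continue
        # a family with too little data is uninformative, not a veto; any
        # substantive violation in an informative family rejects the site
        uninformative_reasons = {"mother_low_depth", "father_low_depth",
                                 "no_informative_sons", "insufficient_informative"}
        vetoes = [r for r in fam_results
                  if r["status"] == "rejected" and r["reject_reason"] not in uninformative_reasons]
        passing = [r for r in fam_results if r["status"] == "Y_linked"]
        if vetoes:
            chosen = vetoes[0]
        elif passing:
            chosen = passing[0]
        else:
            chosen = fam_results[0]
        agg = {
            "chrom": chrom,
            "pos": pos,
            "x_allele": chosen["x_allele"],
            "y_allele": chosen["y_allele"],
            "n_sons_support": sum(r["n_sons_support"] for r in fam_results),
            "n_sons_informative": sum(r["n_sons_informative"] for r in fam_results),
            "n_daughters_checked": sum(r["n_daughters_checked"] for r in fam_results),
            "status": chosen["status"],
            "reject_reason": chosen["reject_reason"],
        }
        rows.append(agg)
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "x_allele", "y_allele", "n_sons_support",
                 "n_sons_informative", "n_daughters_checked", "status", "reject_reason"],
    )


def partition_reads(
    overlap: pd.DataFrame,
    sites: pd.DataFrame,
    all_read_ids: pd.Series | list | None = None,
) -> pd.DataFrame:
    """Assign read pairs to Y / X / ambiguous / uninformative bins.

    ``overlap`` has one row per (read pair, overlapped variant site) with the
    observed base; both mates of a pair share a read_id, so a mate inherits
    its pair's bin. A pair is Y iff every overlapped Y-linked diagnostic site
    shows the y allele (at least one site), X iff every site shows the x
    allele; any conflict or third allele makes it ambiguous. Pairs in
    ``all_read_ids`` absent from the diagnostic overlap are uninformative.
    """
    diag = sites[sites["status"] == "Y_linked"][["chrom", "pos", "x_allele", "y_allele"]]
    merged = overlap.merge(diag, on=["chrom", "pos"], how="inner")
    if merged.empty:
        assigned = pd.DataFrame(columns=["read_id", "bin", "supporting_sites"])
    else:
        merged["is_y"] = merged["base"] == merged["y_allele"]
        merged["is_x"] = merged["base"] == merged["x_allele"]
        grp = merged.groupby("read_id").agg(
            supporting_sites=("pos", "size"),
            all_y=("is_y", "all"),
            all_x=("is_x", "all"),
        )
        third = ~(merged["is_y"] | merged["is_x"])
        if third.any():
            for rid in merged.loc[third, "read_id"].unique()[:5]:
                logger.debug("read %s observed a third allele at a diagnostic site", rid)
        grp["bin"] = "ambiguous"
        grp.loc[grp["all_y"], "bin"] = "Y"
        grp.loc[grp["all_x"] & ~grp["all_y"], "bin"] = "X"
        assigned = grp.reset_index()[["read_id", "bin", "supporting_sites"]]
    if all_read_ids is not None:
        universe = pd.Series(all_read_ids, dtype=str).drop_duplicates()
        rest = universe[~universe.isin(assigned["read_id"])]
        assigned = pd.concat(
            [assigned, pd.DataFrame({"read_id": rest, "bin": "uninformative",
                                     "supporting_sites": 0})],
            ignore_index=True,
        )
    return assigned


def build_consensus(
    pileup: np.ndarray,
    gene_id: str = "gene",
    min_depth: int = 3,
) -> YConsensus:
    """Majority-rule consensus over a CDS from a (length × 4) base-count pileup.

    A position is called when its depth is at least ``min_depth`` and the
    majority base exceeds half the depth; ties and thin positions are 'N'.
    An empty pileup yields an all-N consensus (with a log warning), not an
    error.
    """
    pileup = np.asarray(pileup)
    if pileup.ndim != 2 or pileup.shape[1] != 4:
        raise ValueError("pileup must be (length, 4)")
    depth = pileup.sum(axis=1)
    if depth.sum() == 0:
        logger.warning("%s: no Y-binned reads; consensus is all N", gene_id)
    best = pileup.argmax(axis=1)
    best_count = pileup.max(axis=1)
    # strict majority and no tie for the top base
    n_at_max = (pileup == best_count[:, None]).sum(axis=1)
    called = (depth >= min_depth) & (best_count * 2 > depth) & (n_at_max == 1)
    seq = np.where(called, np.array(list(BASES))[best], "N")
    sequence = "".join(seq)
    frac = float(called.mean()) if len(called) else 0.0
    return YConsensus(gene_id=gene_id, sequence=sequence, depth=depth, fraction_called=frac)


def consensus_from_cross(
    cross_result,
    assignments: pd.DataFrame,
    gene_id: str,
    min_depth: int = 3,
    samples: list[str] | None = None,
) -> YConsensus:
    """Build the Y consensus of one gene from Y-binned simulated reads."""
    gc = cross_result.genes[gene_id]
    y_ids = set(assignments.loc[assignments["bin"] == "Y", "read_id"])
    pileup = np.zeros((gc.length, 4), dtype=np.int64)
    rl = None
    for sid, rs in gc.reads.items():
        if samples is not None and sid not in samples:
            continue
        keep = np.array(
            [f"{sid}|{gene_id}|{k}" in y_ids for k in range(rs.n_pairs)], dtype=bool
        )
        if not keep.any():
            continue
        rl = rs.bases1.shape[1]
        offs = np.arange(rl)
        for starts, bases in ((rs.starts1[keep], rs.bases1[keep]),
                              (rs.starts2[keep], rs.bases2[keep])):
            idx = starts[:, None] + offs
            np.add.at(pileup, (idx.ravel(), bases.ravel().astype(np.int64)), 1)
    return build_consensus(pileup, gene_id=gene_id, min_depth=min_depth)


def validate_against_truth(
    sites: pd.DataFrame,
    truth_sites: pd.DataFrame,
    consensus: dict[str, YConsensus] | None = None,
    true_y: dict[str, str] | None = None,
) -> dict[str, float]:
    """Site precision/recall of Y_linked calls and consensus base accuracy.

    Precision/recall compare called (chrom, pos, y_allele) against the truth
    table. Base accuracy is computed over non-N consensus positions against
    the true Y haplotype where both are supplied.
    """
    called = sites[sites["status"] == "Y_linked"]
    call_set = set(zip(called["chrom"], called["pos"], called["y_allele"]))
    truth_set = set(zip(truth_sites["chrom"], truth_sites["pos"], truth_sites["y_allele"]))
    tp = len(call_set & truth_set)
    precision = tp / len(call_set) if call_set else 0.0
    recall = tp / len(truth_set) if truth_set else 0.0
    report = {"site_precision": precision, "site_recall": recall,
              "n_called": len(call_set), "n_truth": len(truth_set)}
    if consensus is not None and true_y is not None:
        correct = total = 0
        for gid, cons in consensus.items():
            truth_seq = true_y.get(gid)
            if truth_seq is None:
                continue
            for a, b in zip(cons.sequence, truth_seq):
                if a == "N":
                    continue
                total += 1
                correct += a == b
        report["base_accuracy"] = correct / total if total else 0.0
        report["n_called_bases"] = total
    return report
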