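"""Genetic-code helpers shared by the simulator and the substitution-rate estimator.

Uses the universal nuclear code from Biopython. All functions operate on
upper-case DNA codon strings; anything containing a character outside ACGT
(ambiguity codes, gaps, N) is treated as unusable by callers.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

BASES = "ACGT"
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
CODON_TO_AA = dict(_TABLE.forward_table)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"


def translate_codon(codon: str) -> str | None:
    """Amino acid for a codon, '*' for stops, None if not a clean ACGT codon."""
    return CODON_TO_AA.get(codon)


def is_sense(codon: str) -> bool:
    return codon in _TABLE.forward_table


def single_step_changes(codon: str):
    """All 9 single-nucleotide neighbours of a sense codon.

    Yields (position, new_base, new_codon, kind) with kind in
    {"syn", "nonsyn", "stop"}.
    """
    aa = CODON_TO_AA[codon]
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            new = codon[:pos] + base + codon[pos + 1 :]
            if new in STOP_CODONS:
                kind = "stop"
            elif CODON_TO_AA[new] == aa:
                kind = "syn"
            else:
                kind = "nonsyn"
            yield pos, base, new, kind


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """Nei–Gojobori synonymous / nonsynonymous site counts for one codon.

    Each codon position contributes (number of synonymous changes)/3
    synonymous sites; changes creating a stop codon count as nonsynonymous,
    so S + N = 3 exactly.
    """
    n_syn = sum(1 for *_, kind in single_step_changes(codon) if kind == "syn")
    s = n_syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pathway_diff_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts (NG86).

    Averages the per-step classification over all orderings of the differing
    positions; orderings that pass through a stop codon are excluded. If every
    ordering is blocked by stops, the average falls back to all orderings.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order, allow_stops):
        syn = nonsyn = 0
        cur = codon_a
        for pos in order:
            new = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if new in STOP_CODONS:
                if not allow_stops:
                    return None
                nonsyn += 1
            elif CODON_TO_AA[new] == CODON_TO_AA[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = new
        return syn, nonsyn

    for allow_stops in (False, True):
        results = [
            r
            for order in itertools.permutations(diff_pos)
            if (r := walk(order, allow_stops)) is not None
        ]
        if results:
            syn = sum(r[0] for r in results) / len(results)
            nonsyn = sum(r[1] for r in results) / len(results)
            return syn, nonsyn
    raise AssertionError("unreachable")  # pragma: no cover


def split_codons(seq: str) -> list[str]:
    """Split an in-frame nucleotide string into codons (length must be %3==0)."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]
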