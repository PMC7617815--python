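"""Forward simulator for the sex-chromosome analysis pipeline.

Generates, with known ground truth, every input the downstream modules
consume: X/Y/outgroup gametolog coding triplets evolved under per-branch
synonymous divergence and dN/dS targets; a two-generation cross (XY father,
XX mother, genome-sequenced F1 and transcriptome-sequenced F2 progeny) with
paired-end reads and per-site allele-depth tables; a chromosome-scale genetic
map with recombining distal segments flanking a suppressed centre; and
negative-binomial allele-resolved expression counts with region-specific Y
degeneration.

All randomness flows from a single ``numpy.random.Generator``; identical
configuration (including seed) reproduces outputs byte for byte.

Coding-sequence evolution uses a proposal/acceptance process: a proposed
single-nucleotide change is accepted at relative rate 1 if synonymous, omega
if nonsynonymous, and 0 if it would create a stop codon. Branch lengths are
tuned by expectation (event intensity set analytically from the ancestral
site counts), so per-gene realized divergence remains stochastic.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from ._codon import SENSE_CODONS, codon_site_counts, single_step_changes

__all__ = [
    "ConfigurationError",
    "BranchTargets",
    "CrossConfig",
    "MapGeometry",
    "ExpressionConfig",
    "SimConfig",
    "SimGene",
    "simulate_gametolog_triplets",
    "simulate_cross",
    "simulate_genetic_map",
    "simulate_expression",
    "simulate_gene_positions",
    "map_rate_at",
    "map_cm_at",
]

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}


class ConfigurationError(ValueError):
    """Invalid or internally inconsistent simulation configuration."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class BranchTargets:
    """Divergence targets for one region's gametolog triplets.

    ds_xy:    total expected X↔Y synonymous divergence (subs/syn site),
              split evenly between the X and Y branches.
    ds_x_og:  total expected X↔outgroup synonymous divergence.
    omega_*:  dN/dS acceptance ratio on the X, Y and outgroup branches.
    """

    ds_xy: float
    ds_x_og: float
    omega_x: float
    omega_y: float
    omega_og: float

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"branch target {name}={v} must be finite and >= 0")
        if self.ds_x_og < self.ds_xy / 2:
            raise ConfigurationError(
                "ds_x_og must be >= ds_xy/2 (outgroup branch length would be negative)"
            )


@dataclass
class CrossConfig:
    n_f1_genomic: int = 10
    n_f2_transcriptomic: int = 50
    coverage_genomic: float = 20.0
    coverage_rna: float = 20.0
    read_length: int = 150
    error_rate: float = 0.001

    def validate(self) -> None:
        if self.n_f1_genomic < 0 or self.n_f2_transcriptomic < 0:
            raise ConfigurationError("progeny counts must be >= 0")
        if self.n_f1_genomic + self.n_f2_transcriptomic < 2:
            raise ConfigurationError("need at least one son and one daughter")
        if self.coverage_genomic <= 0 or self.coverage_rna <= 0:
            raise ConfigurationError("coverage must be > 0")
        if self.read_length <= 0:
            raise ConfigurationError("read_length must be > 0")
        if not 0 <= self.error_rate < 1:
            raise ConfigurationError("error_rate must be in [0, 1)")


@dataclass
class MapGeometry:
    """Piecewise-constant recombination landscape of an X-like chromosome."""

    chrom_length: int = 370_597_487
    distal_p_length: int = 25_600_000
    distal_q_length: int = 15_000_000
    rate_distal: float = 2.0  # cM/Mb in both distal segments
    rate_center: float = 0.0  # cM/Mb in the pericentromeric segment
    n_markers: int = 400
    cm_noise_sd: float = 0.25  # cM, truncated-normal noise on marker cM
    chrom: str = "ChrX"

    def validate(self) -> None:
        if min(self.chrom_length, self.distal_p_length, self.distal_q_length) <= 0:
            raise ConfigurationError("all lengths must be > 0")
        if self.distal_p_length + self.distal_q_length >= self.chrom_length:
            raise ConfigurationError("distal segments must not cover the chromosome")
        if self.rate_distal < 0 or self.rate_center < 0:
            raise ConfigurationError("rates must be >= 0")
        if self.n_markers < 10:
            raise ConfigurationError("n_markers must be >= 10")

    @property
    def boundaries(self) -> tuple[int, int]:
        return self.distal_p_length, self.chrom_length - self.distal_q_length


@dataclass
class ExpressionConfig:
    mean_tpm: float = 100.0  # expected counts per allele copy
    dispersion: float = 0.1  # NB dispersion; 0 -> Poisson
    # expected reads per library mapping outside the simulated sex-linked
    # genes; dominates library size, as autosomal transcription does in
    # real data, so CPM does not cancel genuine sex differences
    library_background: float = 1e6
    y_degeneration: dict[str, float] = field(
        default_factory=lambda: {"PAR": 1.0, "Xpr": 0.6, "qXdr": 0.2, "autosome": 1.0}
    )

    def validate(self) -> None:
        if self.mean_tpm <= 0:
            raise ConfigurationError("mean_tpm must be > 0")
        if self.library_background < 0:
            raise ConfigurationError("library_background must be >= 0")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        for region, frac in self.y_degeneration.items():
            if not 0 <= frac <= 1:
                raise ConfigurationError(f"y_degeneration[{region}]={frac} not in [0, 1]")


def _default_branch_targets() -> dict[str, BranchTargets]:
    # Region parameterization of the simulated study system: the distal q-arm
    # region diverged first (higher X:Y dS, stronger Y degeneration), the
    # pericentromeric region later; pseudoautosomal genes still recombine
    # (X == Y) and share the outgroup divergence of the X-linked genes.
    return {
        "PAR": BranchTargets(0.0, 0.124, 0.221, 0.221, 0.221),
        "Xpr": BranchTargets(0.063, 0.120, 0.315, 0.591, 0.285),
        "qXdr": BranchTargets(0.091, 0.123, 0.267, 0.408, 0.233),
    }


@dataclass
class SimConfig:
    seed: int = 1
    n_genes_per_region: dict[str, int] = field(
        default_factory=lambda: {"PAR": 150, "Xpr": 150, "qXdr": 150}
    )
    codons_per_gene: int = 500
    branch_targets: dict[str, BranchTargets] = field(default_factory=_default_branch_targets)
    cross: CrossConfig = field(default_factory=CrossConfig)
    map_geometry: MapGeometry = field(default_factory=MapGeometry)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    maternal_snp_rate: float = 0.002  # per-bp neutral heterozygous SNPs in the mother

    def validate(self) -> None:
        if self.codons_per_gene < 10:
            raise ConfigurationError("codons_per_gene must be >= 10")
        for region, n in self.n_genes_per_region.items():
            if n <= 0:
                raise ConfigurationError(f"n_genes_per_region[{region}] must be > 0")
            if region not in self.branch_targets:
                raise ConfigurationError(f"no branch targets for region {region}")
        for targets in self.branch_targets.values():
            targets.validate()
        self.cross.validate()
        self.map_geometry.validate()
        self.expression.validate()

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "branch_targets" in d:
            d["branch_targets"] = {
                k: BranchTargets(**v) if isinstance(v, dict) else v
                for k, v in d["branch_targets"].items()
            }
        for key, sub in (("cross", CrossConfig), ("map_geometry", MapGeometry),
                         ("expression", ExpressionConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# coding-sequence evolution


@dataclass
class BranchEvents:
    """Realized substitution record for one branch of one gene."""

    n_syn: int = 0
    n_nonsyn: int = 0
    s_sites: float = 0.0  # NG86 synonymous sites of the branch-start sequence
    n_sites: float = 0.0

    @property
    def ds(self) -> float:
        return self.n_syn / self.s_sites if self.s_sites else 0.0

    @property
    def dn(self) -> float:
        return self.n_nonsyn / self.n_sites if self.n_sites else 0.0


@dataclass
class SimGene:
    gene_id: str
    region: str
    ancestor: str
    x_cds: str
    y_cds: str
    og_cds: str
    branches: dict[str, BranchEvents]

    @property
    def realized_ds_xy(self) -> float:
        return self.branches["X"].ds + self.branches["Y"].ds


def _codon_changes(codon: str, omega: float):
    """Weighted single-step changes from a sense codon (stop changes dropped)."""
    out = []
    for pos, base, new, kind in single_step_changes(codon):
        if kind == "stop":
            continue
        w = 1.0 if kind == "syn" else omega
        if w > 0:
            out.append((pos, new, kind, w))
    return out


def _evolve_branch(
    codons: list[str], ds_target: float, omega: float, rng: np.random.Generator
) -> tuple[list[str], BranchEvents]:
    """Evolve a codon sequence to an expected synonymous divergence.

    The number of accepted events is Poisson with intensity chosen so that the
    expected count of synonymous events equals ds_target × (synonymous sites
    of the starting sequence); which events are synonymous is stochastic.
    """
    n_codons = len(codons)
    s_sites = sum(codon_site_counts(c)[0] for c in codons)
    n_sites = 3.0 * n_codons - s_sites
    events = BranchEvents(s_sites=s_sites, n_sites=n_sites)
    if ds_target == 0:
        return list(codons), events

    codons = list(codons)
    changes = [_codon_changes(c, omega) for c in codons]
    weights = np.array([sum(ch[3] for ch in cl) for cl in changes])
    syn_weight = sum(
        sum(1.0 for ch in cl if ch[2] == "syn") for cl in changes
    )
    if syn_weight == 0:
        raise ConfigurationError("no synonymous changes available; dS target unreachable")
    lam = ds_target * s_sites * weights.sum() / syn_weight
    n_events = int(rng.poisson(lam))
    for _ in range(n_events):
        total = weights.sum()
        if total <= 0:
            break
        cum = np.cumsum(weights)
        ci = int(np.searchsorted(cum, rng.random() * total, side="right"))
        cl = changes[ci]
        ws = np.array([ch[3] for ch in cl])
        k = int(np.searchsorted(np.cumsum(ws), rng.random() * ws.sum(), side="right"))
        _, new_codon, kind, _ = cl[k]
        codons[ci] = new_codon
        changes[ci] = _codon_changes(new_codon, omega)
        weights[ci] = sum(ch[3] for ch in changes[ci])
        if kind == "syn":
            events.n_syn += 1
        else:
            events.n_nonsyn += 1
    return codons, events


def simulate_gametolog_triplets(
    config: SimConfig,
    region: str,
    rng: np.random.Generator | None = None,
    n_genes: int | None = None,
) -> list[SimGene]:
    """Simulate X/Y/outgroup coding triplets for one region.

    Topology ((X, Y), OG): an ancestral CDS of sense codons is evolved
    independently along the X and Y branches (each an expected ds_xy/2 of
    synonymous divergence, with the branch's omega) and along the outgroup
    branch (expected ds_x_og − ds_xy/2). The per-gene truth records realized
    event counts and divergences per branch.
    """
    config.validate()
    if region not in config.branch_targets:
        raise ConfigurationError(f"unknown region {region!r}")
    targets = config.branch_targets[region]
    rng = rng if rng is not None else config.rng()
    n_genes = n_genes if n_genes is not None else config.n_genes_per_region.get(region, 100)
    og_len = targets.ds_x_og - targets.ds_xy / 2
    genes = []
    sense = np.array(SENSE_CODONS)
    for i in range(n_genes):
        ancestor = list(rng.choice(sense, size=config.codons_per_gene))
        x_codons, x_ev = _evolve_branch(ancestor, targets.ds_xy / 2, targets.omega_x, rng)
        y_codons, y_ev = _evolve_branch(ancestor, targets.ds_xy / 2, targets.omega_y, rng)
        og_codons, og_ev = _evolve_branch(ancestor, og_len, targets.omega_og, rng)
        genes.append(
            SimGene(
                gene_id=f"{region}_g{i:04d}",
                region=region,
                ancestor="".join(ancestor),
                x_cds="".join(x_codons),
                y_cds="".join(y_codons),
                og_cds="".join(og_codons),
                branches={"X": x_ev, "Y": y_ev, "OG": og_ev},
            )
        )
    return genes


def triplet_truth_table(genes: list[SimGene]) -> pd.DataFrame:
    rows = []
    for g in genes:
        for branch, ev in g.branches.items():
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "region": g.region,
                    "branch": branch,
                    "n_syn": ev.n_syn,
                    "n_nonsyn": ev.n_nonsyn,
                    "s_sites": ev.s_sites,
                    "n_sites": ev.n_sites,
                    "ds": ev.ds,
                    "dn": ev.dn,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross simulation


_CODE_LUT = np.full(128, 255, dtype=np.uint8)
for _b, _i in _BASE_TO_CODE.items():
    _CODE_LUT[ord(_b)] = _i


def seq_to_codes(seq: str) -> np.ndarray:
    return _CODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)].copy()


def codes_to_seq(codes: np.ndarray) -> str:
    return "".join(BASES[int(c)] for c in codes)


@dataclass
class ReadSet:
    """Paired-end reads of one individual over one gene, in gene coordinates.

    Mate 2 is stored in reference orientation; FASTQ export reverse-complements
    it. ``hap`` records which of the individual's haplotypes each pair came
    from (truth only; not visible to the pipeline).
    """

    starts1: np.ndarray
    starts2: np.ndarray
    bases1: np.ndarray  # (n, read_length) uint8
    bases2: np.ndarray
    hap: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.starts1)


@dataclass
class GeneCross:
    gene_id: str
    region: str
    length: int
    haplotypes: dict[str, np.ndarray]  # X_ref, Y, X_m1, X_m2
    sample_haps: dict[str, tuple[str, str]]  # sample -> its two haplotype names
    var_positions: np.ndarray
    y_sites: pd.DataFrame  # pos, x_allele, y_allele (true diagnostic sites)
    reads: dict[str, ReadSet]


@dataclass
class CrossResult:
    pedigree: pd.DataFrame
    genes: dict[str, GeneCross]
    observations: pd.DataFrame  # chrom, pos, sample_id, A, C, G, T, depth
    overlap: pd.DataFrame  # read_id, chrom, pos, base, sample_id
    truth_sites: pd.DataFrame  # chrom, pos, x_allele, y_allele

    def read_ids(self, samples: list[str] | None = None) -> pd.Series:
        ids = []
        for gid, gc in self.genes.items():
            for sid, rs in gc.reads.items():
                if samples is not None and sid not in samples:
                    continue
                ids.extend(f"{sid}|{gid}|{k}" for k in range(rs.n_pairs))
        return pd.Series(ids, dtype=str)


def build_pedigree(cross: CrossConfig, family: str = "fam1") -> pd.DataFrame:
    rows = [
        {"sample_id": "father", "family": family, "father": ".", "mother": ".",
         "sex": "M", "role": "father", "generation": "P", "datatype": "genomic"},
        {"sample_id": "mother", "family": family, "father": ".", "mother": ".",
         "sex": "F", "role": "mother", "generation": "P", "datatype": "genomic"},
    ]
    for i in range(cross.n_f1_genomic):
        rows.append(
            {"sample_id": f"f1_{i + 1:02d}", "family": family, "father": "father",
             "mother": "mother", "sex": "M" if i % 2 == 0 else "F", "role": "offspring",
             "generation": "F1", "datatype": "genomic"}
        )
    for i in range(cross.n_f2_transcriptomic):
        rows.append(
            {"sample_id": f"f2_{i + 1:02d}", "family": family, "father": "father",
             "mother": "mother", "sex": "M" if i % 2 == 0 else "F", "role": "offspring",
             "generation": "F2", "datatype": "rna"}
        )
    ped = pd.DataFrame(rows)
    progeny = ped[ped["role"] == "offspring"]
    if (progeny["sex"] == "M").sum() == 0 or (progeny["sex"] == "F").sum() == 0:
        raise ConfigurationError("cross must include at least one son and one daughter")
    return ped


def _maternal_haplotypes(
    x_ref: np.ndarray, y: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two maternal X copies: the reference X plus neutral heterozygous SNPs.

    SNP positions avoid X/Y-divergent sites (so true diagnostic sites stay
    clean) and never create an in-frame stop codon.
    """
    L = len(x_ref)
    m1, m2 = x_ref.copy(), x_ref.copy()
    candidates = np.flatnonzero(x_ref == y)
    n_snps = rng.binomial(len(candidates), rate * L / max(len(candidates), 1))
    n_snps = min(n_snps, len(candidates))
    positions = rng.choice(candidates, size=n_snps, replace=False)
    stops = {"TAA", "TAG", "TGA"}
    for pos in positions:
        target = m1 if rng.integers(2) == 0 else m2
        for _ in range(4):
            alt = (target[pos] + rng.integers(1, 4)) % 4
            c0 = 3 * (pos // 3)
            codon = target[c0 : c0 + 3].copy()
            codon[pos - c0] = alt
            if codes_to_seq(codon) not in stops:
                target[pos] = alt
                break
    return m1, m2


def _simulate_reads(
    hap: np.ndarray, coverage: float, cross: CrossConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Paired-end reads from one haplotype at the given haploid coverage."""
    L = len(hap)
    rl = min(cross.read_length, L)
    n_pairs = rng.poisson(coverage * L / (2 * rl))
    frag = np.minimum(2 * rl + rng.integers(0, 41, size=n_pairs), L)
    starts1 = rng.integers(0, L - frag + 1)
    starts2 = starts1 + frag - rl
    offsets = np.arange(rl)
    bases1 = hap[starts1[:, None] + offsets]
    bases2 = hap[starts2[:, None] + offsets]
    if cross.error_rate > 0:
        for bases in (bases1, bases2):
            err = rng.random(bases.shape) < cross.error_rate
            n_err = int(err.sum())
            if n_err:
                bases[err] = (bases[err] + rng.integers(1, 4, size=n_err)) % 4
    return starts1, starts2, bases1, bases2


def _pileup_at(
    positions: np.ndarray, rs: ReadSet, read_length: int
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Allele depths at positions and per-mate overlap rows for one read set.

    Returns (counts[len(positions), 4], rows of (pair_index, pos, base)).
    """
    counts = np.zeros((len(positions), 4), dtype=np.int64)
    rows: list[tuple[int, int, int]] = []
    for starts, bases in ((rs.starts1, rs.bases1), (rs.starts2, rs.bases2)):
        if len(starts) == 0:
            continue
        for j, pos in enumerate(positions):
            rel = pos - starts
            mask = (rel >= 0) & (rel < read_length)
            if not mask.any():
                continue
            idx = np.flatnonzero(mask)
            vals = bases[idx, rel[idx]]
            counts[j] += np.bincount(vals, minlength=4)
            rows.extend(zip(idx.tolist(), [int(pos)] * len(idx), vals.tolist()))
    return counts, rows


def simulate_cross(
    config: SimConfig,
    genes: list[SimGene],
    rng: np.random.Generator | None = None,
) -> CrossResult:
    """Simulate sequencing of a two-generation cross over the gametolog genes.

    The father carries the reference X and the Y haplotype of each gene; the
    mother carries two X copies with additional neutral heterozygous SNPs.
    Sons inherit the Y plus one maternal X, daughters the paternal X plus one
    maternal X. Genome-coverage individuals are sampled evenly per haplotype;
    transcriptome-coverage individuals have the Y haplotype down-weighted by
    the region's expression degeneration factor. Reads are placed by
    construction, so per-site allele depths and the read/site overlap table
    are emitted directly (no aligner involved).
    """
    config.validate()
    if not genes:
        raise ConfigurationError("no genes supplied to simulate_cross")
    rng = rng if rng is not None else config.rng()
    cross = config.cross
    ped = build_pedigree(cross)
    ydeg = config.expression.y_degeneration

    gene_data: dict[str, GeneCross] = {}
    obs_frames = []
    overlap_frames = []
    truth_rows = []
    for g in genes:
        x_ref = seq_to_codes(g.x_cds)
        y = seq_to_codes(g.y_cds)
        L = len(x_ref)
        m1, m2 = _maternal_haplotypes(x_ref, y, config.maternal_snp_rate, rng)
        haps = {"X_ref": x_ref, "Y": y, "X_m1": m1, "X_m2": m2}

        y_pos = np.flatnonzero(x_ref != y)
        mat_pos = np.flatnonzero((m1 != x_ref) | (m2 != x_ref))
        var_positions = np.unique(np.concatenate([y_pos, mat_pos]))
        y_sites = pd.DataFrame(
            {
                "pos": y_pos,
                "x_allele": [BASES[int(b)] for b in x_ref[y_pos]],
                "y_allele": [BASES[int(b)] for b in y[y_pos]],
            }
        )
        for _, row in y_sites.iterrows():
            truth_rows.append(
                {"chrom": g.gene_id, "pos": int(row["pos"]),
                 "x_allele": row["x_allele"], "y_allele": row["y_allele"]}
            )

        sample_haps: dict[str, tuple[str, str]] = {}
        reads: dict[str, ReadSet] = {}
        for _, s in ped.iterrows():
            sid = s["sample_id"]
            if s["role"] == "father":
                hap_names = ("X_ref", "Y")
            elif s["role"] == "mother":
                hap_names = ("X_m1", "X_m2")
            elif s["sex"] == "M":
                hap_names = ("Y", "X_m1" if rng.integers(2) == 0 else "X_m2")
            else:
                hap_names = ("X_ref", "X_m1" if rng.integers(2) == 0 else "X_m2")
            sample_haps[sid] = hap_names

            base_cov = (
                cross.coverage_genomic if s["datatype"] == "genomic" else cross.coverage_rna
            ) / 2.0
            parts = []
            for hi, hname in enumerate(hap_names):
                cov = base_cov
                if s["datatype"] == "rna" and hname == "Y":
                    cov *= ydeg.get(g.region, 1.0)
                st1, st2, b1, b2 = _simulate_reads(haps[hname], cov, cross, rng)
                parts.append((st1, st2, b1, b2, np.full(len(st1), hi, dtype=np.int8)))
            rs = ReadSet(
                starts1=np.concatenate([p[0] for p in parts]),
                starts2=np.concatenate([p[1] for p in parts]),
                bases1=np.concatenate([p[2] for p in parts]),
                bases2=np.concatenate([p[3] for p in parts]),
                hap=np.concatenate([p[4] for p in parts]),
            )
            reads[sid] = rs

            counts, rows = _pileup_at(var_positions, rs, min(cross.read_length, L))
            if len(var_positions):
                obs_frames.append(
                    pd.DataFrame(
                        {
                            "chrom": g.gene_id,
                            "pos": var_positions,
                            "sample_id": sid,
                            "A": counts[:, 0],
                            "C": counts[:, 1],
                            "G": counts[:, 2],
                            "T": counts[:, 3],
                        }
                    )
                )
            if rows:
                arr = np.array(rows, dtype=np.int64)
                overlap_frames.append(
                    pd.DataFrame(
                        {
                            "read_id": [f"{sid}|{g.gene_id}|{k}" for k in arr[:, 0]],
                            "chrom": g.gene_id,
                            "pos": arr[:, 1],
                            "base": [BASES[b] for b in arr[:, 2]],
                            "sample_id": sid,
                        }
                    )
                )

        gene_data[g.gene_id] = GeneCross(
            gene_id=g.gene_id,
            region=g.region,
            length=L,
            haplotypes=haps,
            sample_haps=sample_haps,
            var_positions=var_positions,
            y_sites=y_sites,
            reads=reads,
        )

    observations = (
        pd.concat(obs_frames, ignore_index=True)
        if obs_frames
        else pd.DataFrame(columns=["chrom", "pos", "sample_id", "A", "C", "G", "T"])
    )
    observations["depth"] = observations[list("ACGT")].sum(axis=1)
    overlap = (
        pd.concat(overlap_frames, ignore_index=True)
        if overlap_frames
        else pd.DataFrame(columns=["read_id", "chrom", "pos", "base", "sample_id"])
    )
    truth_sites = pd.DataFrame(truth_rows, columns=["chrom", "pos", "x_allele", "y_allele"])
    return CrossResult(
        pedigree=ped,
        genes=gene_data,
        observations=observations,
        overlap=overlap,
        truth_sites=truth_sites,
    )


# ---------------------------------------------------------------------------
# genetic map simulation


def map_rate_at(geometry: MapGeometry, x: np.ndarray) -> np.ndarray:
    """Recombination rate (cM/Mb) of the piecewise-constant landscape at bp x."""
    x = np.asarray(x, dtype=float)
    b1, b2 = geometry.boundaries
    rate = np.full_like(x, geometry.rate_center, dtype=float)
    rate[x < b1] = geometry.rate_distal
    rate[x >= b2] = geometry.rate_distal
    return rate


def map_cm_at(geometry: MapGeometry, x: np.ndarray) -> np.ndarray:
    """Cumulative genetic position (cM) at bp x: the integral of the rate."""
    x = np.asarray(x, dtype=float)
    b1, b2 = geometry.boundaries
    rd, rc = geometry.rate_distal / 1e6, geometry.rate_center / 1e6
    cm = np.where(
        x < b1,
        rd * x,
        np.where(x < b2, rd * b1 + rc * (x - b1), rd * b1 + rc * (b2 - b1) + rd * (x - b2)),
    )
    return cm


@dataclass
class MapSimResult:
    markers: pd.DataFrame  # marker_id, linkage_group, cm_female, cm_male
    sequences: dict[str, str]  # marker_id -> marker sequence
    hits: pd.DataFrame  # 12-column tabular hit table (1-based coordinates)
    truth: pd.DataFrame  # marker_id, true_pos, linkage
    geometry: MapGeometry


def _marker_positions(geometry: MapGeometry, n: int) -> np.ndarray:
    """Deterministic quantile placement with density ∝ rate + floor.

    Markers are denser where recombination is higher (they are transcript
    markers recovered from linkage data), with a floor density so the
    suppressed centre keeps enough markers to estimate a (near-zero) rate.
    """
    b1, b2 = geometry.boundaries
    floor = 0.15 * (geometry.rate_distal if geometry.rate_distal > 0 else 1.0)
    w = np.array(
        [geometry.rate_distal + floor, geometry.rate_center + floor, geometry.rate_distal + floor]
    )
    seg_start = np.array([0.0, b1, b2])
    seg_len = np.array([b1, b2 - b1, geometry.chrom_length - b2], dtype=float)
    mass = w * seg_len
    cdf = np.concatenate([[0.0], np.cumsum(mass)]) / mass.sum()
    q = (np.arange(n) + 0.5) / n
    seg = np.searchsorted(cdf, q, side="right") - 1
    seg = np.clip(seg, 0, 2)
    frac = (q - cdf[seg]) / (cdf[seg + 1] - cdf[seg])
    return np.floor(seg_start[seg] + frac * seg_len[seg]).astype(np.int64)


def simulate_genetic_map(
    config: SimConfig, rng: np.random.Generator | None = None
) -> MapSimResult:
    """Simulate a genetic map, marker sequences and an alignment hit table.

    Marker cM positions are the closed-form integral of the piecewise rate
    landscape at the marker bp positions, plus truncated-normal noise
    (sd = ``cm_noise_sd``, bounded at ±3 sd, floored at 0). Each marker gets
    1–3 exon-like hits whose minimum start is the true position; a controlled
    fraction of markers receive additional hits that fail the identity or
    length filters, exercising the anchoring rules downstream.
    """
    config.validate()
    g = config.map_geometry
    rng = rng if rng is not None else config.rng()
    n = g.n_markers
    pos = _marker_positions(g, n)
    cm_true = map_cm_at(g, pos)
    if g.cm_noise_sd > 0:
        noise = np.clip(rng.normal(0, g.cm_noise_sd, size=n), -3 * g.cm_noise_sd, 3 * g.cm_noise_sd)
        cm = np.maximum(cm_true + noise, 0.0)
    else:
        cm = cm_true
    b1, _ = g.boundaries
    marker_ids = [f"M{i + 1:05d}" for i in range(n)]
    in_par = pos < b1
    markers = pd.DataFrame(
        {
            "marker_id": marker_ids,
            "linkage_group": "LGX",
            "cm_female": cm,
            "cm_male": np.where(in_par, cm, np.nan),
        }
    )
    base_arr = np.array(list(BASES))
    sequences = {
        mid: "".join(rng.choice(base_arr, size=200)) for mid in marker_ids
    }

    hit_rows = []
    for i, mid in enumerate(marker_ids):
        n_exons = int(rng.integers(1, 4))
        offsets = np.concatenate([[0], np.cumsum(rng.integers(200, 800, size=n_exons - 1))])
        qpos = 1
        for off in offsets:
            length = int(rng.integers(120, 400))
            sstart = int(pos[i] + off) + 1  # 1-based in the hit table
            hit_rows.append(
                (mid, g.chrom, round(float(rng.uniform(97.5, 100.0)), 2), length, 0, 0,
                 qpos, qpos + length - 1, sstart, sstart + length - 1, 1e-50, 200.0)
            )
            qpos += length
        u = rng.random()
        if u < 0.10:  # identity below the >97% filter
            sstart = int(rng.integers(0, g.chrom_length - 500)) + 1
            hit_rows.append(
                (mid, g.chrom, round(float(rng.uniform(90.0, 96.9)), 2), 250, 8, 1,
                 1, 250, sstart, sstart + 249, 1e-20, 90.0)
            )
        elif u < 0.15:  # alignment below the 100 bp length filter
            sstart = int(rng.integers(0, g.chrom_length - 200)) + 1
            hit_rows.append(
                (mid, g.chrom, 98.5, int(rng.integers(30, 100)), 0, 0,
                 1, 80, sstart, sstart + 79, 1e-10, 60.0)
            )
    hits = pd.DataFrame(
        hit_rows,
        columns=["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                 "qstart", "qend", "sstart", "send", "evalue", "bitscore"],
    )
    truth = pd.DataFrame(
        {
            "marker_id": marker_ids,
            "true_pos": pos,
            "linkage": np.where(in_par, "pseudoautosomal", "sex_linked"),
        }
    )
    return MapSimResult(markers=markers, sequences=sequences, hits=hits, truth=truth, geometry=g)


# ---------------------------------------------------------------------------
# expression simulation


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion <= 1e-12:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_expression(
    config: SimConfig,
    genes: list[SimGene] | pd.DataFrame,
    rng: np.random.Generator | None = None,
    samples: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Allele-resolved negative-binomial expression counts.

    Each X allele copy of a gene draws NB counts with mean ``mean_tpm`` and
    the configured dispersion; the single Y copy in males draws with mean
    ``y_degeneration[region] × mean_tpm``. Females carry two X copies whose
    draws are summed into ``counts_x``. Returns a tidy record table with
    library sizes (column totals per sample).
    """
    config.validate()
    rng = rng if rng is not None else config.rng()
    if isinstance(genes, pd.DataFrame):
        gene_df = genes[["gene_id", "region"]]
    else:
        gene_df = pd.DataFrame({"gene_id": [g.gene_id for g in genes],
                                "region": [g.region for g in genes]})
    if samples is None:
        n = config.cross.n_f2_transcriptomic
        samples = pd.DataFrame(
            {"sample_id": [f"f2_{i + 1:02d}" for i in range(n)],
             "sex": ["M" if i % 2 == 0 else "F" for i in range(n)]}
        )
    exp = config.expression
    rows = []
    for _, s in samples.iterrows():
        for _, grow in gene_df.iterrows():
            delta = exp.y_degeneration.get(grow["region"], 1.0)
            if s["sex"] == "M":
                cx = int(_nb_draw(rng, exp.mean_tpm, exp.dispersion, None))
                cy = int(_nb_draw(rng, delta * exp.mean_tpm, exp.dispersion, None))
            else:
                cx = int(_nb_draw(rng, exp.mean_tpm, exp.dispersion, None)) + int(
                    _nb_draw(rng, exp.mean_tpm, exp.dispersion, None)
                )
                cy = 0
            rows.append(
                {"gene_id": grow["gene_id"], "region": grow["region"],
                 "sample_id": s["sample_id"], "sex": s["sex"],
                 "counts_x": cx, "counts_y": cy}
            )
    records = pd.DataFrame(rows)
    background = {
        s: int(rng.poisson(exp.library_background)) if exp.library_background > 0 else 0
        for s in samples["sample_id"]
    }
    lib = records.groupby("sample_id")[["counts_x", "counts_y"]].transform("sum")
    records["library_size"] = (
        lib["counts_x"] + lib["counts_y"] + records["sample_id"].map(background)
    ).clip(lower=1)
    return records


# ---------------------------------------------------------------------------
# gene placement for density scans

# study-system defaults: gene-rich recombining chromosome ends, gene-poor
# pericentromeric centre, and a typical autosome for comparison scans
DEFAULT_GENE_DENSITIES = {"distal_p": 17.8, "distal_q": 17.8, "pericentromeric": 6.6}
DEFAULT_AUTOSOME_LENGTH = 193_566_110
DEFAULT_AUTOSOME_GENE_DENSITY = 18.3


def simulate_gene_positions(
    intervals: list[tuple[int, int, str]],
    densities: dict[str, float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Place gene start positions uniformly within labeled intervals.

    ``densities`` maps interval labels to genes/Mb; counts per interval are
    Poisson with that intensity. Returns a frame with start, end (start+1)
    and label, sorted by position.
    """
    rows = []
    for start, end, label in intervals:
        dens = densities.get(label)
        if dens is None or end <= start:
            continue
        n = rng.poisson(dens * (end - start) / 1e6)
        pos = np.sort(rng.integers(start, end, size=n))
        for p in pos:
            rows.append({"start": int(p), "end": int(p) + 1, "label": label})
    return pd.DataFrame(rows, columns=["start", "end", "label"])
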