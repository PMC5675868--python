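"""Seeded generators for every input the pipeline consumes, with truth manifests.

The generators emulate Firmicutes-plasmid-like data: replicons carrying a
relaxase CDS optionally preceded by one or two small co-oriented auxiliary
genes (short intergenic gaps, occasional stop/start overlap = translational
coupling), decoy CDSs of random composition, transfer-origin-like sequences
with a planted palindrome and planted direct repeats at ~61% AT, and noisy
hydrodynamic observations / sedimentation-equilibrium gradients.

Everything is driven by one numpy PCG64 generator seeded from the config, so
identical seeds give byte-identical outputs.  Each planted feature is
recorded in a truth manifest, making closed-loop recovery testable at zero
noise.  The mutation model is substitution-only (no indels), and decoy
proteins are drawn uniformly over the 20 amino acids, which guarantees their
separation from planted homologs under the default search thresholds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .errors import ConfigError, InputError
from .hydro import (HydroConditions, HydroObservation, R_CGS, S_UNIT,
                    forward_s)
from .seqio import (GeneFeature, RepliconAnnotation, reverse_complement,
                    reverse_complement_annotation, write_annotation)
from ._seed_proteins import AUX1_SEED, AUX2_SEED, RELAXASE_SEED

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE11.forward_table.items()):
    _CODONS_FOR.setdefault(aa, []).append(codon)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic replicon generator.

    Default prevalences mirror the observed architecture of MOB-family
    relaxase neighborhoods: roughly a quarter of relaxase genes carry an
    adjacent aux2-like gene, and roughly a fifth of those carry an
    additional aux1-like gene further upstream.
    """

    seed: int = 0
    n_replicons: int = 20
    p_aux2_upstream: float = 0.27
    p_aux1_upstream: float = 0.22
    intergenic_bp_range: tuple[int, int] = (0, 200)
    p_coupled: float = 0.3
    mutation_rate: float = 0.05
    n_decoys_per_replicon: int = 3
    replicon_length: int | None = None   # cap; None = grow as needed

    def __post_init__(self) -> None:
        for p in (self.p_aux2_upstream, self.p_aux1_upstream, self.p_coupled,
                  self.mutation_rate):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        lo, hi = self.intergenic_bp_range
        if lo < 0 or hi < lo:
            raise ConfigError("invalid intergenic_bp_range")


@dataclass
class TruthManifest:
    """Ground truth for one generated dataset.

    ``genes``: columns replicon, gene_id, family in
    {relaxase, aux1-like, aux2-like, decoy}.
    ``orit_motifs``: planted motif positions per oriT-like sequence.
    """

    genes: pd.DataFrame
    orit_motifs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["region_id", "motif", "position"]))

    def family_ids(self, family: str) -> set[str]:
        sel = self.genes["family"] == family
        return set(self.genes.loc[sel, "gene_id"])


def random_protein(length: int, rng: np.random.Generator) -> str:
    """Uniform-composition protein starting with M (decoy model)."""
    aas = rng.choice(list(AMINO_ACIDS), size=length - 1)
    return "M" + "".join(aas)


def generate_rhh_protein(length: int, rng: np.random.Generator | int,
                         strand_pool: tuple[str, ...] = ("V", "I"),
                         helix_pool: tuple[str, ...] = ("A", "E", "L"),
                         junction: tuple[str, str] = ("RKK", "KK")) -> str:
    """Compose a protein whose N-terminus carries a strand–helix–helix motif.

    Built from the predictor's own propensity classes: an M start, ~7
    strand-favoring residues, a turn linker, two ~12-residue helix-favoring
    segments separated by a proline/glycine-rich linker, with >= 3 K/R
    placed at the helix1-end/helix2-start junction; the remainder is random.
    The residue pools are configurable so that distinct protein families can
    share the motif geometry without sharing sequence (keeps synthetic
    families separable by homology search).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if length < 45:
        raise InputError("RHH protein needs length >= 45")
    strand = "".join(rng.choice(strand_pool, size=7))
    linker1 = "".join(rng.choice(["G", "N", "S"], size=4))
    helix1 = "".join(rng.choice(helix_pool, size=12 - len(junction[0]))) + junction[0]
    linker2 = "".join(rng.choice(["P", "G", "N"], size=5))
    helix2 = junction[1] + "".join(rng.choice(helix_pool, size=12 - len(junction[1])))
    core = "M" + strand + linker1 + helix1 + linker2 + helix2
    tail = "".join(rng.choice(list(AMINO_ACIDS), size=length - len(core)))
    return core + tail


def mutate_protein(protein: str, rate: float, rng: np.random.Generator) -> str:
    """Per-residue substitutions at the given rate; the start M is preserved."""
    out = list(protein)
    for i in range(1, len(out)):
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def encode_cds(protein: str, rng: np.random.Generator) -> str:
    """Back-translate a protein to a CDS: ATG start, random synonymous codons,
    TAA stop."""
    if not protein.startswith("M"):
        raise InputError("planted proteins must start with M")
    codons = ["ATG"]
    for aa in protein[1:]:
        options = _CODONS_FOR[aa]
        codons.append(options[rng.integers(len(options))])
    codons.append("TAA")
    return "".join(codons)


def _background_dna(length: int, rng: np.random.Generator,
                    at: float = 0.60) -> str:
    probs = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(rng.choice(["A", "C", "G", "T"], size=length, p=probs))


class _RepliconBuilder:
    def __init__(self, replicon_id: str, rng: np.random.Generator) -> None:
        self.replicon_id = replicon_id
        self.rng = rng
        self.parts: list[str] = []
        self.pos = 0  # 0-based length so far
        self.features: list[GeneFeature] = []
        self._n = 0

    def pad(self, lo: int, hi: int) -> None:
        n = int(self.rng.integers(lo, hi + 1))
        self.parts.append(_background_dna(n, self.rng))
        self.pos += n

    def gene(self, protein: str, strand: str = "+",
             overlap_previous: bool = False) -> str:
        """Emit a CDS; with ``overlap_previous`` its start codon shares one
        base with the stop codon of the gene just emitted (...TA[A=start]TG...)."""
        self._n += 1
        gid = f"{self.replicon_id}_g{self._n:02d}"
        dna = encode_cds(protein, self.rng)
        if overlap_previous:
            assert strand == "+" and self.parts and self.parts[-1].endswith("TAA")
            self.parts.append(dna[1:])          # reuse the terminal A of TAA
            start = self.pos                    # 1-based: stop's last base
            self.pos += len(dna) - 1
        else:
            if strand == "-":
                dna = reverse_complement(dna)
            self.parts.append(dna)
            start = self.pos + 1
            self.pos += len(dna)
        feat = GeneFeature(gene_id=gid, start=start, end=start + len(dna) - 1,
                           strand=strand, protein=protein)
        self.features.append(feat)
        return gid

    def gap(self, n: int) -> None:
        self.parts.append(_background_dna(n, self.rng))
        self.pos += n

    def build(self) -> RepliconAnnotation:
        return RepliconAnnotation(self.replicon_id, "".join(self.parts),
                                  self.features)


def generate_replicons(config: SynthConfig
                       ) -> tuple[list[RepliconAnnotation], TruthManifest]:
    """Generate annotated replicons with planted relaxase/aux architectures.

    Each replicon carries one mutated copy of the fixed seed relaxase
    protein; with probability ``p_aux2_upstream`` an aux2-like gene directly
    upstream and, conditional on that, with ``p_aux1_upstream`` an aux1-like
    gene further upstream separated by a draw from ``intergenic_bp_range``.
    With ``p_coupled`` the aux2/relaxase junction overlaps stop and start
    codons.  Half of the replicons (in expectation) are emitted on the
    reverse strand to exercise both orientations.
    """
    rng = np.random.default_rng(config.seed)
    annotations = []
    records = []
    for r in range(config.n_replicons):
        rid = f"synthrep{r + 1:03d}"
        b = _RepliconBuilder(rid, rng)
        b.pad(80, 160)
        decoys_before = config.n_decoys_per_replicon // 2
        decoys_after = config.n_decoys_per_replicon - decoys_before
        for _ in range(decoys_before):
            gid = b.gene(random_protein(int(rng.integers(50, 151)), rng),
                         strand=str(rng.choice(["+", "-"])))
            records.append((rid, gid, "decoy"))
            b.pad(40, 120)

        has_aux2 = rng.random() < config.p_aux2_upstream
        has_aux1 = has_aux2 and rng.random() < config.p_aux1_upstream
        lo, hi = config.intergenic_bp_range
        if has_aux1:
            gid = b.gene(mutate_protein(AUX1_SEED, config.mutation_rate, rng))
            records.append((rid, gid, "aux1-like"))
            b.gap(int(rng.integers(lo, hi + 1)))
        if has_aux2:
            gid = b.gene(mutate_protein(AUX2_SEED, config.mutation_rate, rng))
            records.append((rid, gid, "aux2-like"))
            coupled = rng.random() < config.p_coupled
            if not coupled:
                b.gap(int(rng.integers(lo, hi + 1)))
            gid = b.gene(mutate_protein(RELAXASE_SEED, config.mutation_rate, rng),
                         overlap_previous=coupled)
        else:
            gid = b.gene(mutate_protein(RELAXASE_SEED, config.mutation_rate, rng))
        records.append((rid, gid, "relaxase"))

        for _ in range(decoys_after):
            b.pad(40, 120)
            gid = b.gene(random_protein(int(rng.integers(50, 151)), rng),
                         strand=str(rng.choice(["+", "-"])))
            records.append((rid, gid, "decoy"))
        b.pad(100, 200)
        ann = b.build()
        if config.replicon_length is not None and len(ann) > config.replicon_length:
            raise ConfigError(
                f"{rid}: packed length {len(ann)} exceeds replicon_length "
                f"{config.replicon_length}")
        if rng.random() < 0.5:
            ann = reverse_complement_annotation(ann)
        annotations.append(ann)
    genes = pd.DataFrame(records, columns=["replicon", "gene_id", "family"])
    if genes["gene_id"].duplicated().any():
        raise ConfigError("manifest gene ids are not unique")
    return annotations, TruthManifest(genes)


# ---------------------------------------------------------------------------
# oriT-like sequences

PALINDROME = "TGGTACCA"
DR_MOTIF = "TGTGCAT"
DR_CONTEXT = "TTTATGTGCATT"    # carries DR_MOTIF at offset 4
SITE25 = (201, 225)            # 1-based window holding the planted palindrome


def generate_orit(seed: int, length: int = 500, plant: bool = True
                  ) -> tuple[str, dict[str, list[int]]]:
    """Generate an oriT-like sequence with planted motifs (~61% AT background).

    Plants one copy of the palindrome inside a fixed 25-bp window, and three
    same-strand copies of the direct-repeat motif in the 5' half, two of
    them embedded in the longer context motif.  Accidental extra copies of
    the planted motifs are scrubbed, so the planted counts are exact.
    Returns (sequence, motif map of 1-based planted positions).
    """
    if length < 300:
        raise InputError("oriT-like sequence needs length >= 300")
    rng = np.random.default_rng(seed)
    seq = list(_background_dna(length, rng, at=0.61))
    if not plant:
        return "".join(seq), {}

    def put(motif: str, pos1: int) -> None:
        seq[pos1 - 1:pos1 - 1 + len(motif)] = motif

    pal_pos = int(rng.integers(SITE25[0], SITE25[1] - len(PALINDROME) + 2))
    put(PALINDROME, pal_pos)
    # pin non-complementary flanks so the planted palindrome is maximal as planted
    seq[pal_pos - 2] = "C"
    seq[pal_pos - 1 + len(PALINDROME)] = "C"
    ctx1 = int(rng.integers(10, 81))
    ctx2 = int(rng.integers(100, 171))
    put(DR_CONTEXT, ctx1)
    put(DR_CONTEXT, ctx2)
    lone = int(rng.integers(180, 194))
    put(DR_MOTIF, lone)
    seq[lone - 1 + len(DR_MOTIF)] = "C"      # break any accidental context embedding
    planted = {
        PALINDROME: [pal_pos],
        DR_MOTIF: sorted([ctx1 + 4, ctx2 + 4, lone]),
        DR_CONTEXT: sorted([ctx1, ctx2]),
        "site25": [SITE25[0], SITE25[1]],
    }
    _scrub(seq, planted, rng)
    return "".join(seq), planted


def _scrub(seq: list[str], planted: dict[str, list[int]],
           rng: np.random.Generator) -> None:
    """Mutate accidental occurrences of planted motifs outside planted windows."""
    protected = set()
    for motif in (PALINDROME, DR_MOTIF, DR_CONTEXT):
        for p in planted.get(motif, []):
            protected.update(range(p - 1, p - 1 + len(motif)))
    for _ in range(100):
        dirty = False
        s = "".join(seq)
        for motif in (DR_MOTIF, PALINDROME, DR_CONTEXT):
            wanted = set(p - 1 for p in planted.get(motif, []))
            i = s.find(motif)
            while i != -1:
                if i not in wanted:
                    free = [j for j in range(i, i + len(motif))
                            if j not in protected]
                    j = free[0]
                    options = [b for b in "ACGT" if b != seq[j]]
                    seq[j] = options[rng.integers(len(options))]
                    dirty = True
                    break
                i = s.find(motif, i + 1)
            if dirty:
                break
        if not dirty:
            return
    raise ConfigError("could not scrub accidental motif copies")


# ---------------------------------------------------------------------------
# hydrodynamic observations

def generate_hydro_samples(n_oligomer: int, monomer_mass: float, f_ratio: float,
                           noise_cv: float, n: int, seed: int,
                           cond: HydroConditions = HydroConditions()
                           ) -> list[HydroObservation]:
    """Draw noisy (s, D) observations of an n-mer from the forward model.

    s comes from the sphere/frictional-ratio model, D from the Svedberg
    relation at the same mass; both get multiplicative Gaussian noise with
    the given coefficient of variation.
    """
    if n_oligomer < 1 or f_ratio < 1:
        raise InputError("need n_oligomer >= 1 and f_ratio >= 1")
    rng = np.random.default_rng(seed)
    M = n_oligomer * monomer_mass
    s_true = forward_s(M, f_ratio, cond)                      # S
    d_true = (s_true * S_UNIT * R_CGS * cond.temperature
              / (M * cond.buoyancy)) * 1e8                    # μm²/s
    out = []
    for i in range(n):
        s_i = s_true * (1.0 + noise_cv * rng.standard_normal())
        d_i = d_true * (1.0 + noise_cv * rng.standard_normal())
        out.append(HydroObservation(f"obs{i + 1:04d}", s_i, d_i, monomer_mass))
    return out


def generate_se_gradient(M: float, vbar: float, rho: float, omega: float,
                         r_range: tuple[float, float], noise_sd: float,
                         seed: int, c0: float = 0.5, baseline: float = 0.0,
                         n_points: int = 80, temperature: float = 293.15
                         ) -> pd.DataFrame:
    """Simulate a single-species SE gradient: a(r) = baseline + c0·e^{σ(r²−r0²)/2}.

    σ = M(1 − v̄ρ)ω²/(RT); radii in cm, ω in rad/s, noise is additive
    Gaussian in signal units.
    """
    rng = np.random.default_rng(seed)
    r = np.linspace(r_range[0], r_range[1], n_points)
    sigma = M * (1.0 - vbar * rho) * omega ** 2 / (R_CGS * temperature)
    signal = baseline + c0 * np.exp(sigma * (r ** 2 - r[0] ** 2) / 2.0)
    signal = signal + noise_sd * rng.standard_normal(n_points)
    return pd.DataFrame({"radius": r, "signal": signal})


# ---------------------------------------------------------------------------
# dataset emission

def write_dataset(config: SynthConfig, out_dir: str | Path) -> TruthManifest:
    """Emit a full synthetic dataset: GFF3+FASTA per replicon, protein FASTA,
    an oriT-like sequence, and TSV truth manifests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotations, manifest = generate_replicons(config)
    prot_lines = []
    for ann in annotations:
        write_annotation(ann, out / f"{ann.replicon_id}.gff3",
                         out / f"{ann.replicon_id}.fasta")
        for f in ann.features:
            if f.protein:
                prot_lines.append(f">{f.gene_id}\n{f.protein}")
    (out / "proteins.faa").write_text("\n".join(prot_lines) + "\n")

    orit_seq, motifs = generate_orit(config.seed, length=500)
    (out / "orit.fasta").write_text(f">synthorit\n{orit_seq}\n")
    motif_rows = [{"region_id": "synthorit", "motif": m, "position": p}
                  for m, positions in motifs.items() for p in positions]
    manifest = dataclasses.replace(
        manifest, orit_motifs=pd.DataFrame(
            motif_rows, columns=["region_id", "motif", "position"]))
    manifest.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    manifest.orit_motifs.to_csv(out / "truth_orit_motifs.tsv", sep="\t",
                                index=False)
    return manifest
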