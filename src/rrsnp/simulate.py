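"""Synthetic two-parent genomes and pooled reduced-representation tag reads.

The generator emulates the study design this package analyses: two inbred
parental genomes differing at ~1 SNP per 5,000 bp plus sparse short indels,
a reference littered with interspersed repeat families (~59% of the genome,
the repeat content of soybean) and a few exact segmental duplications
(paralog traps), blunt-cutter digestion with 70–200 bp size selection, and
33-mer end-tag sequencing whose per-tag read counts follow an overdispersed
Gamma-Poisson (negative binomial) law with extra pile-up on repetitive tags.

Randomness: one root seed; every stage draws from a named substream derived
from it, so adding a stage never shifts another stage's draws and identical
configurations give byte-identical outputs.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._intervals import GenomeIntervals
from .digest import Tag, digest, size_select, tags_of
from .enzymes import BUILTIN_ENZYMES, EnzymeSpec
from .io import FastqRead

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {65: 0, 67: 1, 71: 2, 84: 3}

#: Phred+33 quality symbols of the declared three-level quality model.
QUAL_OK = chr(30 + 33)     # ordinary base, Q30
QUAL_ERR = chr(10 + 33)    # substitution-injected base, Q10
QUAL_N = chr(2 + 33)       # 'N' base, Q2


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named RNG substream: independent of any other stage's draws."""
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic dataset."""

    genome_length: int = 1_000_000
    n_chromosomes: int = 2
    repeat_fraction: float = 0.59        # genome-wide repeat content target
    repeat_family_count: int = 3
    repeat_monomer_length: int = 400
    repeat_divergence: float = 0.05      # per-copy divergence from the family seed
    duplication_count: int = 5           # exact segmental duplications (paralog traps)
    duplication_length: int = 2_000
    snp_rate: float = 1.0 / 5000.0       # parent-vs-parent SNPs per bp
    indel_rate: float = 1.0 / 50_000.0   # sparse short indels per bp
    indel_max_len: int = 3
    mean_tag_coverage: float = 20.0      # mu: mean reads per tag per parent
    gamma_shape: Optional[float] = 1.0   # k; None disables overdispersion
    repeat_coverage_multiplier: float = 10.0
    base_error_rate: float = 0.001
    n_rate: float = 0.0009               # per-base 'N' rate (~2.9% of 33-mers carry an N)
    read_length: int = 33
    seed: int = 42

    def __post_init__(self):
        for name in ("repeat_fraction", "snp_rate", "indel_rate",
                     "base_error_rate", "n_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.mean_tag_coverage <= 0:
            raise ValueError("mean_tag_coverage must be > 0")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0 (or None)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class VariantTruth:
    """A spiked parent-vs-parent difference; the recovery-scoring oracle."""

    chrom: str
    position: int          # 0-based on the reference
    ref: str
    alt: str
    kind: str              # "SNP" or "indel"
    in_footprint: Optional[bool] = None  # inside a selected-tag footprint of both parents


@dataclass
class SimulatedGenomes:
    reference: Dict[str, str]
    alternate: Dict[str, str]
    truth: List[VariantTruth]
    repeats: GenomeIntervals
    duplications: GenomeIntervals      # source+destination intervals of paralog pairs
    #: per chromosome: sorted (ref_position, length_delta) of applied indels
    indel_deltas: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)

    def ref_to_alt(self, chrom: str, pos: int) -> int:
        """Translate a reference coordinate to the alternate haplotype."""
        shift = 0
        for p, d in self.indel_deltas.get(chrom, ()):
            if p < pos:
                shift += d
            else:
                break
        return pos + shift

    @property
    def indel_positions(self) -> Dict[str, List[int]]:
        return {c: [p for p, _ in lst] for c, lst in self.indel_deltas.items()}


def _random_seq_array(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate_array(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each base independently with probability ``rate``."""
    out = arr.copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    if hits.size:
        idx = np.array([_BASE_INDEX[b] for b in out[hits]])
        out[hits] = _BASES[(idx + rng.integers(1, 4, size=hits.size)) % 4]
    return out


def _place_nonoverlapping(
    rng: np.random.Generator,
    chrom_len: int,
    length: int,
    occupied: List[Tuple[int, int]],
    max_tries: int = 50,
) -> Optional[int]:
    """A random start for an interval of ``length`` avoiding ``occupied``."""
    for _ in range(max_tries):
        start = int(rng.integers(0, chrom_len - length))
        end = start + length
        if all(end <= s or start >= e for s, e in occupied):
            occupied.append((start, end))
            return start
    return None


def make_parent_genomes(config: SimConfig) -> SimulatedGenomes:
    """Build reference + alternate haplotypes, truth table and repeat mask.

    Construction order per chromosome: random background; exact segmental
    duplications copied within the reference (paralog traps, kept out of
    the repeat mask); repeat-family copies at ``repeat_divergence`` from a
    family seed monomer, placed without overlap to approximately the target
    repeat fraction; then SNPs and indels spiked into the alternate copy.
    Overlapping edits are resolved by skipping the collision (logged).
    """
    L = config.genome_length
    n_chrom = max(1, config.n_chromosomes)
    chrom_lens = [L // n_chrom] * n_chrom
    chrom_lens[-1] += L - sum(chrom_lens)

    rng_bg = stage_rng(config.seed, "background")
    rng_dup = stage_rng(config.seed, "duplications")
    rng_rep = stage_rng(config.seed, "repeats")
    rng_snp = stage_rng(config.seed, "snps")
    rng_ind = stage_rng(config.seed, "indels")

    reference: Dict[str, np.ndarray] = {}
    occupied: Dict[str, List[Tuple[int, int]]] = {}
    dup_intervals: Dict[str, List[Tuple[int, int]]] = {}
    repeat_intervals: Dict[str, List[Tuple[int, int]]] = {}

    names = [f"chr{i + 1}" for i in range(n_chrom)]
    for name, clen in zip(names, chrom_lens):
        reference[name] = _random_seq_array(rng_bg, clen)
        occupied[name] = []
        dup_intervals[name] = []
        repeat_intervals[name] = []

    # paralog traps: copy a segment verbatim to a second locus
    for _ in range(config.duplication_count):
        src_chrom = names[int(rng_dup.integers(0, n_chrom))]
        dst_chrom = names[int(rng_dup.integers(0, n_chrom))]
        dlen = min(config.duplication_length, min(chrom_lens) // 4)
        if dlen < 100:
            break
        src = _place_nonoverlapping(rng_dup, len(reference[src_chrom]), dlen, occupied[src_chrom])
        if src is None:
            continue
        dst = _place_nonoverlapping(rng_dup, len(reference[dst_chrom]), dlen, occupied[dst_chrom])
        if dst is None:
            continue
        reference[dst_chrom][dst : dst + dlen] = reference[src_chrom][src : src + dlen]
        dup_intervals[src_chrom].append((src, src + dlen))
        dup_intervals[dst_chrom].append((dst, dst + dlen))

    # interspersed repeat families
    monomers = [
        _random_seq_array(rng_rep, config.repeat_monomer_length)
        for _ in range(config.repeat_family_count)
    ]
    target_repeat = config.repeat_fraction * L
    placed = 0
    misses = 0
    while placed < target_repeat and misses < 200 and monomers:
        fam = monomers[int(rng_rep.integers(0, len(monomers)))]
        chrom = names[int(rng_rep.integers(0, n_chrom))]
        start = _place_nonoverlapping(
            rng_rep, len(reference[chrom]), fam.size, occupied[chrom]
        )
        if start is None:
            misses += 1
            continue
        copy = _mutate_array(rng_rep, fam, config.repeat_divergence)
        reference[chrom][start : start + fam.size] = copy
        repeat_intervals[chrom].append((start, start + fam.size))
        placed += fam.size
    if placed < 0.9 * target_repeat and target_repeat > 0:
        logger.warning(
            "repeat placement reached %.1f%% of the %.0f bp target",
            100 * placed / target_repeat, target_repeat,
        )

    # alternate haplotype: SNPs first, then indels (collisions skipped)
    truth: List[VariantTruth] = []
    alternate: Dict[str, str] = {}
    indel_deltas: Dict[str, List[Tuple[int, int]]] = {}
    for name in names:
        ref_arr = reference[name]
        alt_arr = ref_arr.copy()
        snp_pos = np.flatnonzero(rng_snp.random(ref_arr.size) < config.snp_rate)
        for p in snp_pos.tolist():
            ref_base = chr(ref_arr[p])
            bi = _BASE_INDEX[ref_arr[p]]
            alt_base = chr(_BASES[(bi + int(rng_snp.integers(1, 4))) % 4])
            alt_arr[p] = ord(alt_base)
            truth.append(VariantTruth(name, p, ref_base, alt_base, "SNP"))

        snp_set = set(snp_pos.tolist())
        indel_pos = np.flatnonzero(rng_ind.random(ref_arr.size) < config.indel_rate)
        chosen: List[Tuple[int, int, bool]] = []  # (pos, length, is_deletion)
        last_end = -10
        for p in indel_pos.tolist():
            ilen = int(rng_ind.integers(1, config.indel_max_len + 1))
            is_del = bool(rng_ind.integers(0, 2))
            if p <= last_end + 1 or p + ilen + 1 >= ref_arr.size:
                logger.debug("skipping colliding indel at %s:%d", name, p)
                continue
            if any(q in snp_set for q in range(p, p + ilen + 1)):
                logger.debug("skipping indel over SNP at %s:%d", name, p)
                continue
            chosen.append((p, ilen, is_del))
            last_end = p + ilen
        # apply right-to-left so earlier reference coordinates stay valid
        alt_list = alt_arr.tolist()
        deltas: List[Tuple[int, int]] = []
        for p, ilen, is_del in reversed(chosen):
            if is_del:
                ref_seg = "".join(chr(b) for b in ref_arr[p : p + ilen + 1])
                del alt_list[p + 1 : p + 1 + ilen]
                truth.append(VariantTruth(name, p, ref_seg, ref_seg[0], "indel"))
                deltas.append((p, -ilen))
            else:
                ins = _random_seq_array(rng_ind, ilen)
                ref_seg = chr(ref_arr[p])
                alt_seg = ref_seg + "".join(chr(b) for b in ins)
                alt_list[p + 1 : p + 1] = ins.tolist()
                truth.append(VariantTruth(name, p, ref_seg, alt_seg, "indel"))
                deltas.append((p, ilen))
        indel_deltas[name] = sorted(deltas)
        alternate[name] = "".join(chr(b) for b in alt_list)

    reference_str = {c: arr.tobytes().decode("ascii") for c, arr in reference.items()}
    truth.sort(key=lambda v: (v.chrom, v.position))
    return SimulatedGenomes(
        reference=reference_str,
        alternate=alternate,
        truth=truth,
        repeats=GenomeIntervals(repeat_intervals),
        duplications=GenomeIntervals(dup_intervals),
        indel_deltas=indel_deltas,
    )


# ---------------------------------------------------------------------------
# discoverability annotation


def selected_tag_footprints(
    genome: Dict[str, str],
    enzyme: EnzymeSpec,
    size_range: Tuple[int, int] = (70, 200),
    tag_len: int = 33,
) -> Tuple[List[Tag], GenomeIntervals]:
    """Tags of the size-selected digest and their footprint intervals."""
    selected = size_select(digest(genome, enzyme), *size_range)
    tags = tags_of(selected, tag_len)
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for t in tags:
        by_chrom.setdefault(t.chrom, []).append((t.start, t.end))
    return tags, GenomeIntervals(by_chrom)


def mark_discoverable(
    genomes: SimulatedGenomes,
    enzyme: EnzymeSpec,
    size_range: Tuple[int, int] = (70, 200),
    tag_len: int = 33,
) -> Tuple[GenomeIntervals, GenomeIntervals]:
    """Set each truth variant's in_footprint flag.

    A variant is discoverable only if reads cover it in *both* parents:
    its reference coordinate must lie in a selected-tag footprint of the
    reference digest and its (indel-shifted) alternate coordinate in a
    selected-tag footprint of the alternate digest. Returns the two
    footprint interval collections (reference coords, alternate coords).
    """
    _, ref_fp = selected_tag_footprints(genomes.reference, enzyme, size_range, tag_len)
    _, alt_fp = selected_tag_footprints(genomes.alternate, enzyme, size_range, tag_len)
    for v in genomes.truth:
        in_ref = ref_fp.covers(v.chrom, v.position)
        in_alt = alt_fp.covers(v.chrom, genomes.ref_to_alt(v.chrom, v.position))
        v.in_footprint = bool(in_ref and in_alt)
    return ref_fp, alt_fp


# ---------------------------------------------------------------------------
# read simulation


def sample_tag_counts(
    rng: np.random.Generator,
    n: int,
    mean: float,
    shape: Optional[float],
    multiplier: np.ndarray | float = 1.0,
) -> np.ndarray:
    """Per-tag read counts under the Gamma-Poisson coverage model.

    count_i ~ Poisson(mean * multiplier_i * g_i) with g_i ~ Gamma(shape,
    mean 1); shape None gives plain Poisson (the dispersion-free limit).
    """
    lam = np.full(n, float(mean)) * np.asarray(multiplier, dtype=float)
    if shape is not None:
        lam = lam * rng.gamma(shape, 1.0 / shape, size=n)
    return rng.poisson(lam)


@dataclass
class TagRecord:
    """Bookkeeping row for one sequenced tag of one parent."""

    parent: str
    chrom: str
    start: int
    end: int
    side: str
    repetitive: bool
    read_count: int


def simulate_tag_reads(
    genomes: SimulatedGenomes,
    enzyme: EnzymeSpec | str = "CviRI",
    size_range: Tuple[int, int] = (70, 200),
    config: SimConfig | None = None,
) -> Tuple[List[FastqRead], List[TagRecord]]:
    """Pooled 33-mer end-tag reads from both parents.

    Both parents are digested with the same enzyme and size range and
    pooled 50:50 (each tag of each parent draws its own read count, with
    the same mean). Tags whose footprint overlaps the repeat mask draw
    their Poisson mean multiplied by ``repeat_coverage_multiplier`` —
    the repeat-driven pile-up seen in real coverage data. Each emitted
    base substitutes to a random other base with ``base_error_rate`` and
    to 'N' with ``n_rate``; qualities follow the fixed three-level model.
    """
    config = config or SimConfig()
    if isinstance(enzyme, str):
        enzyme = BUILTIN_ENZYMES[enzyme]
    rng_cov = stage_rng(config.seed, "coverage")
    rng_err = stage_rng(config.seed, "errors")
    tag_len = config.read_length

    # P2 tag coordinates are alternate-haplotype coordinates
    parents = [("P1", genomes.reference), ("P2", genomes.alternate)]
    reads: List[FastqRead] = []
    records: List[TagRecord] = []
    for parent_name, genome in parents:
        tags, _ = selected_tag_footprints(genome, enzyme, size_range, tag_len)
        tags = [t for t in tags if not t.collapsed and len(t.sequence) == tag_len]
        mult = np.ones(len(tags))
        for i, t in enumerate(tags):
            # repeat mask is in reference coordinates; the alternate differs
            # only by sparse short indels, so footprints are mapped back
            # through the indel offsets before the overlap test.
            if parent_name == "P1":
                start, end = t.start, t.end
            else:
                rstart = _alt_to_ref(genomes, t.chrom, t.start)
                start, end = rstart, rstart + tag_len
            if genomes.repeats.overlaps(t.chrom, start, end):
                mult[i] = config.repeat_coverage_multiplier
        counts = sample_tag_counts(
            rng_cov, len(tags), config.mean_tag_coverage, config.gamma_shape, mult
        )
        for i, (t, c) in enumerate(zip(tags, counts.tolist())):
            records.append(
                TagRecord(parent_name, t.chrom, t.start, t.end, t.side,
                          bool(mult[i] > 1.0), c)
            )
            if c == 0:
                continue
            base = np.frombuffer(t.sequence.encode("ascii"), dtype=np.uint8)
            mat = np.tile(base, (c, 1))
            qual = np.full((c, tag_len), ord(QUAL_OK), dtype=np.uint8)
            if config.base_error_rate > 0:
                errs = rng_err.random((c, tag_len)) < config.base_error_rate
                if errs.any():
                    rr, cc = np.nonzero(errs)
                    idx = np.array([_BASE_INDEX[b] for b in mat[rr, cc]])
                    mat[rr, cc] = _BASES[(idx + rng_err.integers(1, 4, size=rr.size)) % 4]
                    qual[rr, cc] = ord(QUAL_ERR)
            if config.n_rate > 0:
                ns = rng_err.random((c, tag_len)) < config.n_rate
                if ns.any():
                    mat[ns] = ord("N")
                    qual[ns] = ord(QUAL_N)
            for j in range(c):
                name = f"{parent_name}:{t.chrom}:{t.start}-{t.end}:{t.side}:{j}"
                reads.append(
                    FastqRead(
                        name,
                        mat[j].tobytes().decode("ascii"),
                        qual[j].tobytes().decode("ascii"),
                    )
                )
    return reads, records


def _alt_to_ref(genomes: SimulatedGenomes, chrom: str, pos: int) -> int:
    """Approximate inverse of ref_to_alt (exact outside indel loci)."""
    shift = 0
    for p, d in genomes.indel_deltas.get(chrom, ()):
        if p + shift < pos:
            shift += d
        else:
            break
    return pos - shift


# ---------------------------------------------------------------------------
# overdispersion fit


@dataclass
class GammaFit:
    shape: float   # math.inf when the counts show no overdispersion
    mean: float
    var_mean_ratio: float


def fit_gamma_overdispersion(per_tag_counts: Sequence[int] | np.ndarray) -> GammaFit:
    """Method-of-moments Gamma-Poisson fit to per-tag read counts.

    Under count ~ Poisson(mu*g), g ~ Gamma(k, mean 1): E = mu and
    Var = mu + mu^2/k, so k_hat = m^2 / (v - m). Counts at or below the
    Poisson variance floor (v <= m, e.g. constant counts) return an
    infinite-shape sentinel. Include zero-count tags when they are known:
    truncating zeros biases the moments.
    """
    counts = np.asarray(per_tag_counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least two per-tag counts")
    m = float(counts.mean())
    v = float(counts.var(ddof=1))
    if m <= 0 or v <= m:
        return GammaFit(shape=math.inf, mean=m, var_mean_ratio=(v / m if m else math.nan))
    return GammaFit(shape=m * m / (v - m), mean=m, var_mean_ratio=v / m)
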