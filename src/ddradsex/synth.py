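"""Synthetic ddRAD data with planted sex-linked truth.

This module emulates the study design used for sex-linked marker discovery in
species with homomorphic sex chromosomes: a diploid genome reduced by a
double restriction digest (SphI at the 5' end, EcoRI at the 3' end), a
450-550 bp fragment size selection, and strand-specific paired-end 150 bp
sequencing with 5 bp inline barcodes.  Loci are planted on an autosome, on
the shared sex chromosome (Z or X), or on the sex-limited chromosome (W or
Y), and every simulated read carries its source locus in its name so that
downstream recovery can be scored against the planted truth.

Sex-limited loci are modelled as sequences absent from the homologous
chromosome (not as cut-site polymorphisms): under ZW, females carry one copy
of every W locus and one Z copy, males two Z copies and no W; under XY the
pattern is mirrored.  A hemizygous copy therefore receives half the expected
read depth of a diploid locus, which is the signal the depth filter uses.

Per-individual sequencing effort is controlled by ``target_read_pairs``:
exactly that many read pairs are generated per individual, allocated across
locus copies by a multinomial draw (per-copy counts are then approximately
Poisson).  Between-individual variation in library yield — the dominant mode
of depth variation in real ddRAD cohorts — is modelled by varying
``target_read_pairs`` across individuals; optional within-individual
overdispersion is available through ``depth_dispersion``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .reads import FastqRecord, PHRED_OFFSET, reverse_complement

DNA_ALPHABET = "ACGT"
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_CODE_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode_seq(sequence: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array of base codes 0..3."""
    arr = _BASE_CODE[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains characters outside {A,C,G,T}")
    return arr


def decode_seq(codes: np.ndarray) -> str:
    return _CODE_BASE[codes].tobytes().decode()


# ---------------------------------------------------------------------------
# Enzymes and in-silico digestion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme modelled as a recognition site plus a cut offset.

    The cut is placed after ``cut_offset`` bases of the recognition sequence
    on the + strand; the downstream fragment therefore begins with
    ``recognition[cut_offset:]`` (its 5' remnant) and the upstream fragment
    ends with ``recognition[:cut_offset]`` (its 3' remnant).
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut offset must lie within the recognition site")

    @property
    def remnant_5prime(self) -> str:
        return self.recognition[self.cut_offset:]

    @property
    def remnant_3prime(self) -> str:
        return self.recognition[: self.cut_offset]


SPHI = Enzyme("SphI", "GCATGC", 5)    # GCATG^C
ECORI = Enzyme("EcoRI", "GAATTC", 1)  # G^AATTC

TERMINUS = "terminus"


@dataclass(frozen=True)
class Fragment:
    """A digest fragment: 0-based half-open interval plus the identity of the
    enzyme (or sequence terminus) that produced each end."""

    start: int
    end: int
    end5_type: str
    end3_type: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _site_occurrences(sequence: str, site: str) -> list[int]:
    """All (possibly overlapping) + strand occurrences of a recognition site."""
    hits, pos = [], sequence.find(site)
    while pos != -1:
        hits.append(pos)
        pos = sequence.find(site, pos + 1)
    return hits


def in_silico_digest(sequence: str, enzyme5: Enzyme, enzyme3: Enzyme) -> list[Fragment]:
    """Digest a sequence with two enzymes, returning fragments in order.

    Fragments partition the input (their lengths sum to the sequence length);
    each internal boundary lies at an enzyme's cut offset within an
    occurrence of its recognition site.  Only + strand occurrences are
    scanned; the canonical sites are palindromic.
    """
    if set(sequence) - set(DNA_ALPHABET + "N"):
        raise ValueError("sequence contains characters outside {A,C,G,T,N}")
    if enzyme5.recognition == enzyme3.recognition:
        raise ValueError("the two enzymes must have distinct recognition sequences")
    cuts: list[tuple[int, str]] = []
    for enzyme in (enzyme5, enzyme3):
        for occ in _site_occurrences(sequence, enzyme.recognition):
            cuts.append((occ + enzyme.cut_offset, enzyme.name))
    cuts.sort()
    # Drop duplicate cut positions (cannot arise for distinct sites with
    # different remnants, but keeps the partition well-formed regardless).
    deduped: list[tuple[int, str]] = []
    for pos, name in cuts:
        if not deduped or pos != deduped[-1][0]:
            deduped.append((pos, name))
    boundaries = [(0, TERMINUS)] + deduped + [(len(sequence), TERMINUS)]
    fragments = []
    for (start, left), (end, right) in zip(boundaries[:-1], boundaries[1:]):
        if end > start:
            fragments.append(Fragment(start, end, end5_type=left, end3_type=right))
    return fragments


def size_select(
    fragments: Sequence[Fragment],
    window: tuple[int, int],
    enzyme5: Enzyme = SPHI,
    enzyme3: Enzyme = ECORI,
) -> list[Fragment]:
    """Retain sequenceable fragments: dual-cut, correctly oriented, in-window.

    The strand-specific library construction only amplifies fragments with
    the 5' enzyme's cut site at the 5' end and the 3' enzyme's at the 3' end,
    so single-enzyme and wrong-orientation fragments are excluded regardless
    of length.
    """
    low, high = window
    if low > high:
        raise ValueError("size-selection window low must be <= high")
    return [
        f for f in fragments
        if low <= f.length <= high
        and f.end5_type == enzyme5.name
        and f.end3_type == enzyme3.name
    ]


# ---------------------------------------------------------------------------
# Genome and cohort specifications
# ---------------------------------------------------------------------------

@dataclass
class GenomeSpec:
    """Composition of the simulated reduced-representation genome."""

    n_autosomal_loci: int = 200
    n_w_specific_loci: int = 5
    n_z_or_x_loci: int = 0
    system: str = "ZW"
    locus_length_window: tuple[int, int] = (450, 550)
    gc_content: float = 0.5
    snp_rate: float = 0.002
    max_allele_mismatch: int = 4   # alleles of one locus stay assemblable
    min_locus_distance: int = 5    # distinct loci stay separable (> M)

    def __post_init__(self) -> None:
        if min(self.n_autosomal_loci, self.n_w_specific_loci, self.n_z_or_x_loci) < 0:
            raise ValueError("locus counts must be non-negative")
        if self.system not in ("ZW", "XY"):
            raise ValueError("system must be 'ZW' or 'XY'")
        low, high = self.locus_length_window
        if not low < high:
            raise ValueError("locus length window low must be < high")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")

    @property
    def sex_limited_class(self) -> str:
        return "W" if self.system == "ZW" else "Y"

    @property
    def shared_class(self) -> str:
        return "Z" if self.system == "ZW" else "X"

    @property
    def heterogametic_sex(self) -> str:
        return "female" if self.system == "ZW" else "male"


@dataclass(frozen=True)
class Locus:
    locus_id: str
    chromosome_class: str          # autosome | Z | W | X | Y
    alleles: tuple[str, ...]       # 1 or 2 equal-length sequences

    def __post_init__(self) -> None:
        if not 1 <= len(self.alleles) <= 2:
            raise ValueError("a locus carries one or two allele sequences")
        if len({len(a) for a in self.alleles}) != 1:
            raise ValueError("allele sequences must have equal length")


@dataclass
class ReferenceSet:
    """Planted loci plus the truth table downstream recovery is scored against."""

    loci: list[Locus]
    truth_table: dict[str, str]    # locus_id -> chromosome class
    spec: GenomeSpec

    def sex_limited_ids(self) -> list[str]:
        cls = self.spec.sex_limited_class
        return [i for i, c in self.truth_table.items() if c == cls]

    def by_id(self, locus_id: str) -> Locus:
        return next(l for l in self.loci if l.locus_id == locus_id)


@dataclass
class IndividualSpec:
    individual_id: str
    sex: str
    barcode: str
    target_read_pairs: int
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")
        if len(self.barcode) != 5 or set(self.barcode) - set(DNA_ALPHABET):
            raise ValueError("barcode must be a 5-character string over {A,C,G,T}")
        if self.target_read_pairs <= 0:
            raise ValueError("target_read_pairs must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")


@dataclass
class SimConfig:
    """Sequencing-simulation parameters."""

    seed: int = 0
    read_length: int = 150
    barcode_length: int = 5
    enzyme5: Enzyme = SPHI
    enzyme3: Enzyme = ECORI
    mean_depth_per_locus: float = 15.0   # expected reads per locus copy
    depth_dispersion: float | None = None  # gamma shape for extra overdispersion; None = multinomial only
    phred_quality: int = 37

    def __post_init__(self) -> None:
        min_len = self.barcode_length + len(self.enzyme5.recognition) + 1
        if self.read_length < min_len:
            raise ValueError(f"read_length must be at least {min_len}")
        if self.depth_dispersion is not None and self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive when set")

    @property
    def stitched_length(self) -> int:
        """Length of a barcode-trimmed stitched read."""
        return 2 * self.read_length - self.barcode_length


def stitched_view(locus_sequence: str, config: SimConfig) -> str:
    """The read-visible portion of a locus: R1 span + R2 span, gap removed."""
    r1_span = config.read_length - config.barcode_length
    return locus_sequence[:r1_span] + locus_sequence[-config.read_length:]


# ---------------------------------------------------------------------------
# Reference simulation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return decode_seq(rng.choice(4, size=length, p=probs).astype(np.uint8))


def _contains_site(sequence: str, config: SimConfig) -> bool:
    return (config.enzyme5.recognition in sequence) or (config.enzyme3.recognition in sequence)


def _draw_locus_sequence(rng: np.random.Generator, spec: GenomeSpec, config: SimConfig) -> str:
    """One digest-fragment sequence: 5' remnant + site-free core + 3' remnant."""
    remn5 = config.enzyme5.remnant_5prime
    remn3 = config.enzyme3.remnant_3prime
    low, high = spec.locus_length_window
    while True:
        length = int(rng.integers(low, high + 1))
        core = _random_seq(rng, length - len(remn5) - len(remn3), spec.gc_content)
        seq = remn5 + core + remn3
        if not _contains_site(seq, config):
            return seq


def _mutate_allele(rng: np.random.Generator, sequence: str, spec: GenomeSpec, config: SimConfig) -> str:
    """Derive a second allele by per-base substitution at snp_rate.

    The enzyme remnants are never mutated (a cut-site polymorphism is out of
    scope), no internal recognition site may be created, and the two alleles
    must stay within ``max_allele_mismatch`` read-visible differences so a
    heterozygote still assembles as a single locus.
    """
    remn5, remn3 = config.enzyme5.remnant_5prime, config.enzyme3.remnant_3prime
    lo, hi = len(remn5), len(sequence) - len(remn3)
    for _ in range(100):
        codes = encode_seq(sequence).copy()
        mask = rng.random(len(codes)) < spec.snp_rate
        mask[:lo] = False
        mask[hi:] = False
        if not mask.any():
            return sequence
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
        alt = decode_seq(codes)
        visible_diff = sum(
            x != y for x, y in zip(stitched_view(sequence, config), stitched_view(alt, config))
        )
        if not _contains_site(alt, config) and visible_diff <= spec.max_allele_mismatch:
            return alt
    return sequence


def simulate_reference(spec: GenomeSpec, rng: np.random.Generator, config: SimConfig | None = None) -> ReferenceSet:
    """Generate planted loci for every chromosome class.

    Autosomal and shared-chromosome loci carry one or two alleles (two when
    the snp draw is non-empty); sex-limited loci are single-allele sequences
    shared with no other locus.  All loci fit the size-selection window by
    construction and any two distinct loci differ at more than
    ``min_locus_distance - 1`` read-visible positions, so assembly cannot
    merge them (pairwise check at generation time; colliding loci are
    redrawn).
    """
    config = config or SimConfig()
    low, _ = spec.locus_length_window
    min_needed = 2 * config.read_length - config.barcode_length
    if low < min_needed:
        raise ValueError(
            f"locus length window too small: loci must be at least {min_needed} bp "
            f"to be covered without read overlap"
        )
    if low < len(config.enzyme5.remnant_5prime) + len(config.enzyme3.remnant_3prime) + 1:
        raise ValueError("locus length window too small to fit the enzyme remnants")

    plan = (
        [("autosome", True)] * spec.n_autosomal_loci
        + [(spec.shared_class, True)] * spec.n_z_or_x_loci
        + [(spec.sex_limited_class, False)] * spec.n_w_specific_loci
    )

    def draw(cls: str, polymorphic: bool) -> tuple[str, ...]:
        a = _draw_locus_sequence(rng, spec, config)
        if polymorphic and spec.snp_rate > 0:
            b = _mutate_allele(rng, a, spec, config)
            if b != a:
                return (a, b)
        return (a,)

    alleles_per_locus: list[tuple[str, ...]] = [draw(cls, poly) for cls, poly in plan]

    # Enforce cross-locus separability in read-visible (stitched) space.
    for _ in range(200):
        views = [stitched_view(a, config) for alls in alleles_per_locus for a in alls]
        owner = [i for i, alls in enumerate(alleles_per_locus) for _ in alls]
        mat = np.stack([encode_seq(v) for v in views]) if views else np.empty((0, 0))
        colliding: set[int] = set()
        for i in range(len(views)):
            if owner[i] in colliding:
                continue
            d = (mat[i + 1:] != mat[i]).sum(axis=1)
            for j_off in np.nonzero(d < spec.min_locus_distance)[0]:
                j = i + 1 + int(j_off)
                if owner[j] != owner[i]:
                    colliding.add(owner[j])
        if not colliding:
            break
        for idx in colliding:
            alleles_per_locus[idx] = draw(*plan[idx])
    else:
        raise RuntimeError("could not generate pairwise-separable loci")

    counters: dict[str, int] = {}
    loci, truth = [], {}
    for (cls, _), alleles in zip(plan, alleles_per_locus):
        counters[cls] = counters.get(cls, 0) + 1
        locus_id = f"{cls}_{counters[cls]:04d}"
        loci.append(Locus(locus_id, cls, alleles))
        truth[locus_id] = cls
    return ReferenceSet(loci=loci, truth_table=truth, spec=spec)


def build_genome(ref: ReferenceSet, rng: np.random.Generator, config: SimConfig | None = None,
                 spacer_length: int = 200) -> str:
    """Reassemble a pseudo-chromosome whose double digest + size selection
    yields exactly the reference loci (one allele per locus), for round-trip
    validation of the digest model."""
    config = config or SimConfig()
    e5, e3 = config.enzyme5, config.enzyme3
    parts = []
    for locus in ref.loci:
        while True:
            spacer = _random_seq(rng, spacer_length, ref.spec.gc_content)
            # spacer must not create sites at the junctions either
            chunk = spacer + e5.recognition[: e5.cut_offset] + locus.alleles[0] + e3.recognition[e3.cut_offset:]
            if not _contains_site(spacer, config):
                break
        parts.append(chunk)
    tail = _random_seq(rng, spacer_length, ref.spec.gc_content)
    while _contains_site(tail, config):
        tail = _random_seq(rng, spacer_length, ref.spec.gc_content)
    return "".join(parts) + tail


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def generate_barcodes(n: int, rng: np.random.Generator, length: int = 5, min_distance: int = 3) -> list[str]:
    """Random barcodes with pairwise Hamming distance >= min_distance."""
    chosen: list[np.ndarray] = []
    for _ in range(200 * n):
        cand = rng.integers(0, 4, size=length).astype(np.uint8)
        if all(int((cand != c).sum()) >= min_distance for c in chosen):
            chosen.append(cand)
            if len(chosen) == n:
                return [decode_seq(c) for c in chosen]
    raise RuntimeError(f"could not generate {n} barcodes at distance {min_distance}")


def copies_per_individual(ref: ReferenceSet, sex: str) -> int:
    """Number of locus copies an individual of the given sex carries."""
    spec = ref.spec
    het = spec.heterogametic_sex
    n = 0
    for locus in ref.loci:
        if locus.chromosome_class == "autosome":
            n += 2
        elif locus.chromosome_class == spec.shared_class:
            n += 1 if sex == het else 2
        else:  # sex-limited
            n += 1 if sex == het else 0
    return n


def make_cohort(
    ref: ReferenceSet,
    n_females: int,
    n_males: int,
    config: SimConfig,
    rng: np.random.Generator,
    error_rate: float = 0.0,
    mean_depths: Sequence[float] | None = None,
) -> list[IndividualSpec]:
    """Build a known-sex cohort with distinct barcodes and per-individual
    read targets sized so the expected depth per locus copy is
    ``config.mean_depth_per_locus`` (or the per-individual values given in
    ``mean_depths``, females first)."""
    n = n_females + n_males
    barcodes = generate_barcodes(n, rng)
    sexes = ["female"] * n_females + ["male"] * n_males
    ids = [f"F{i + 1:02d}" for i in range(n_females)] + [f"M{i + 1:02d}" for i in range(n_males)]
    if mean_depths is None:
        mean_depths = [config.mean_depth_per_locus] * n
    if len(mean_depths) != n:
        raise ValueError("mean_depths must have one entry per individual")
    cohort = []
    for ind_id, sex, barcode, depth in zip(ids, sexes, barcodes, mean_depths):
        target = max(1, round(depth * copies_per_individual(ref, sex)))
        cohort.append(IndividualSpec(ind_id, sex, barcode, target, error_rate))
    return cohort


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _genotype(ref: ReferenceSet, ind: IndividualSpec, rng: np.random.Generator) -> list[tuple[str, int, str]]:
    """Per-copy genotype: list of (locus_id, allele_index, allele_sequence).

    Alleles segregate at frequency 1/k: each carried chromosome copy draws
    one of the locus's k allele sequences independently.
    """
    spec = ref.spec
    het = spec.heterogametic_sex
    copies: list[tuple[str, int, str]] = []
    for locus in ref.loci:
        if locus.chromosome_class == "autosome":
            n_copies = 2
        elif locus.chromosome_class == spec.shared_class:
            n_copies = 1 if ind.sex == het else 2
        else:
            n_copies = 1 if ind.sex == het else 0
        for _ in range(n_copies):
            idx = int(rng.integers(0, len(locus.alleles)))
            copies.append((locus.locus_id, idx, locus.alleles[idx]))
    return copies


def _apply_errors(matrix: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    if error_rate <= 0 or matrix.size == 0:
        return matrix
    mask = rng.random(matrix.shape) < error_rate
    n = int(mask.sum())
    if n:
        matrix = matrix.copy()
        matrix[mask] = (matrix[mask] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    return matrix


def simulate_individual_reads(
    ref: ReferenceSet,
    ind: IndividualSpec,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[FastqRecord], list[FastqRecord]]:
    """Simulate exactly ``target_read_pairs`` read pairs for one individual.

    R1 = barcode + the locus 5' prefix, to the read length; R2 = the reverse
    complement of the locus suffix ending at the 3' remnant.  Read names
    encode the source locus and allele (``ind|locus|aK|serial``) purely for
    truth-tracking; downstream analysis never parses them.
    """
    copies = _genotype(ref, ind, rng)
    k = len(copies)
    if k == 0:
        return [], []
    if config.depth_dispersion is not None:
        weights = rng.gamma(config.depth_dispersion, 1.0 / config.depth_dispersion, size=k)
        weights = np.maximum(weights, 1e-12)
    else:
        weights = np.ones(k)
    counts = rng.multinomial(ind.target_read_pairs, weights / weights.sum())

    r1_span = config.read_length - config.barcode_length
    bc = encode_seq(ind.barcode)
    r1_templates = np.empty((k, config.read_length), dtype=np.uint8)
    r2_templates = np.empty((k, config.read_length), dtype=np.uint8)
    for i, (_, _, seq) in enumerate(copies):
        r1_templates[i, : config.barcode_length] = bc
        r1_templates[i, config.barcode_length:] = encode_seq(seq[:r1_span])
        r2_templates[i] = encode_seq(reverse_complement(seq[-config.read_length:]))

    r1_mat = np.repeat(r1_templates, counts, axis=0)
    r2_mat = np.repeat(r2_templates, counts, axis=0)
    r1_mat = _apply_errors(r1_mat, ind.error_rate, rng)
    r2_mat = _apply_errors(r2_mat, ind.error_rate, rng)

    qual = chr(config.phred_quality + PHRED_OFFSET) * config.read_length
    names: list[str] = []
    serial = 0
    for (locus_id, allele_idx, _), c in zip(copies, counts):
        for _ in range(int(c)):
            names.append(f"{ind.individual_id}|{locus_id}|a{allele_idx}|{serial}")
            serial += 1

    r1_bytes = _CODE_BASE[r1_mat].tobytes()
    r2_bytes = _CODE_BASE[r2_mat].tobytes()
    L = config.read_length
    r1_records = [
        FastqRecord(f"{name}/1", r1_bytes[i * L : (i + 1) * L].decode(), qual)
        for i, name in enumerate(names)
    ]
    r2_records = [
        FastqRecord(f"{name}/2", r2_bytes[i * L : (i + 1) * L].decode(), qual)
        for i, name in enumerate(names)
    ]
    return r1_records, r2_records


def simulate_read_records(
    ref: ReferenceSet,
    individuals: Sequence[IndividualSpec],
    config: SimConfig,
) -> tuple[list[FastqRecord], list[FastqRecord]]:
    """Simulate the pooled library in memory (R1 list, R2 list, in sync)."""
    min_len = min(min(len(a) for a in locus.alleles) for locus in ref.loci) if ref.loci else 0
    if ref.loci and min_len < config.stitched_length:
        raise ValueError("reference loci shorter than the stitched read span")
    rng = np.random.default_rng(config.seed)
    all_r1: list[FastqRecord] = []
    all_r2: list[FastqRecord] = []
    for ind in individuals:
        r1, r2 = simulate_individual_reads(ref, ind, config, rng)
        all_r1.extend(r1)
        all_r2.extend(r2)
    return all_r1, all_r2


def write_sample_sheet(individuals: Sequence[IndividualSpec], path: str | Path) -> None:
    pd.DataFrame(
        {
            "individual": [i.individual_id for i in individuals],
            "barcode": [i.barcode for i in individuals],
            "sex": [i.sex for i in individuals],
        }
    ).to_csv(path, sep="\t", index=False)


def write_truth_table(ref: ReferenceSet, path: str | Path) -> None:
    pd.DataFrame(
        {"locus_id": list(ref.truth_table), "class": list(ref.truth_table.values())}
    ).to_csv(path, sep="\t", index=False)


def simulate_reads(
    ref: ReferenceSet,
    individuals: Sequence[IndividualSpec],
    config: SimConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Simulate the pooled library to disk.

    Writes gzip FASTQ R1/R2 for the pooled library, a sample sheet TSV and a
    truth TSV.  Output is byte-identical for identical inputs and seed.
    """
    from .reads import write_fastq

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    r1, r2 = simulate_read_records(ref, individuals, config)
    paths = {
        "r1": out / "library_R1.fastq.gz",
        "r2": out / "library_R2.fastq.gz",
        "samples": out / "samples.tsv",
        "truth": out / "truth.tsv",
    }
    write_fastq(r1, paths["r1"])
    write_fastq(r2, paths["r2"])
    write_sample_sheet(individuals, paths["samples"])
    write_truth_table(ref, paths["truth"])
    return paths
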