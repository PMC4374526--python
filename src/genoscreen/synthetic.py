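"""Synthetic inputs with known ground truth.

Generates haploid reference genomes with an embedded CDS, per-strain variant
call sets (shared parental variants + private planted mutations + sub-quality
noise), Poisson depth tracks with optional tandem duplications, diverged
proteins, and synthetic cell images with planted membrane patches.

All randomness flows from one seed through independent named substreams
(:mod:`genoscreen._rng`), so generators never perturb one another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._rng import substream
from .effects import CdsModel
from .hgvs import (
    DELETION,
    DELINS,
    DUPLICATION,
    INSERTION,
    INVERSION,
    SUBSTITUTION,
    HgvsVariant,
    apply_variant,
    revcomp,
)
from .depth import DepthTrack
from .patches import CellOutline
from .triage import HETEROZYGOUS, HOMOZYGOUS, StrainCallSet, VariantRecord, CdsInterval

__all__ = [
    "ReferenceBundle",
    "StrainTruth",
    "EllipseCell",
    "SyntheticImageSpec",
    "make_reference",
    "table_fixture_cds",
    "plant_mutations",
    "simulate_depth",
    "mutate_protein",
    "render_cells",
]

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ReferenceBundle:
    """A haploid genome with one embedded CDS.

    ``cds_start`` is the 1-based genomic position of CDS base 1;
    ``upstream_len`` bases immediately 5' of it are addressable through
    negative c. coordinates.
    """

    genome: str
    cds_start: int
    cds_length: int
    upstream_len: int
    chrom: str = "chr1"

    def __post_init__(self):
        if self.cds_length % 3 != 0:
            raise ValueError(f"CDS length {self.cds_length} is not a codon multiple")
        if not 1 <= self.cds_start <= len(self.genome) - self.cds_length + 1:
            raise ValueError("CDS does not fit inside the genome")
        if self.upstream_len > self.cds_start - 1:
            raise ValueError("upstream span extends past the genome start")

    @property
    def cds_end(self) -> int:
        return self.cds_start + self.cds_length - 1

    @property
    def cds_seq(self) -> str:
        return self.genome[self.cds_start - 1 : self.cds_end]

    @property
    def upstream_seq(self) -> str:
        return self.genome[self.cds_start - 1 - self.upstream_len : self.cds_start - 1]

    def cds_model(self, id: str = "cds") -> CdsModel:
        return CdsModel(self.cds_seq, self.upstream_seq, id=id)

    def cds_interval(self) -> CdsInterval:
        return CdsInterval(self.chrom, self.cds_start, self.cds_end)

    def c_to_genomic(self, pos: int) -> int:
        """Map a c. coordinate to a 1-based genomic position."""
        if pos == 0:
            raise ValueError("position 0 does not exist")
        return self.cds_start + pos - 1 if pos > 0 else self.cds_start + pos


def make_reference(
    seed: int,
    genome_length: int = 10_000,
    cds_length: int = 300,
    cds_start: int = 2001,
    upstream_len: Optional[int] = None,
    chrom: str = "chr1",
) -> ReferenceBundle:
    """Random genome whose CDS starts with ATG, ends in a stop codon and has
    no internal stop.  Byte-identical for identical seeds."""
    if cds_length % 3 != 0:
        raise ValueError(f"cds_length {cds_length} is not a multiple of 3")
    if cds_length < 6:
        raise ValueError("cds_length must allow a start and a stop codon")
    if cds_start < 1 or cds_start + cds_length - 1 > genome_length:
        raise ValueError("CDS does not fit inside the genome")
    rng = substream(seed, "reference")
    genome = rng.choice(_BASES, size=genome_length)
    n_codons = cds_length // 3
    body = rng.choice(np.array(_SENSE_CODONS), size=n_codons - 2)
    cds = "ATG" + "".join(body) + str(rng.choice(np.array(_STOPS)))
    genome[cds_start - 1 : cds_start - 1 + cds_length] = list(cds)
    if upstream_len is None:
        upstream_len = min(cds_start - 1, 2000)
    return ReferenceBundle("".join(genome), cds_start, cds_length, upstream_len, chrom)


def table_fixture_cds(n_codons: int = 2382, upstream_len: int = 2000) -> CdsModel:
    """Deterministic long CDS fixture for exercising published mutation
    strings: codon 339 is AAA (an A>T at its first base creates a stop) and
    codon 1371 is AAG (a G>T at its third base is the K>N missense)."""
    if n_codons < 2382:
        raise ValueError("fixture needs at least 2382 codons (7146 nt)")
    codons = ["GAA"] * n_codons
    codons[0] = "ATG"
    codons[338] = "AAA"  # codon 339
    codons[1370] = "AAG"  # codon 1371
    codons[-1] = "TAA"
    upstream = ("ACGT" * ((upstream_len + 3) // 4))[:upstream_len]
    return CdsModel("".join(codons), upstream, id="fixture")


# ---------------------------------------------------------------------------
# strain call sets


@dataclass(frozen=True)
class StrainTruth:
    """Ground truth for one simulated strain."""

    strain_id: str
    private_mutations: tuple[HgvsVariant, ...]
    private_records: tuple[VariantRecord, ...]
    shared_parental_variants: tuple[VariantRecord, ...]
    noise_variants: tuple[VariantRecord, ...]

    def call_set(self) -> StrainCallSet:
        return StrainCallSet(
            self.strain_id,
            self.private_records + self.shared_parental_variants + self.noise_variants,
        )


def _snv(genome: str, pos: int, rng, **quality) -> VariantRecord:
    ref = genome[pos - 1]
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return VariantRecord(pos=pos, ref=ref, alt=alt, **quality)


def variant_to_record(ref: ReferenceBundle, v: HgvsVariant) -> VariantRecord:
    """Express a CDS-coordinate variant as a genomic VCF-style record with
    qualities comfortably above the default triage thresholds."""
    g = ref.genome
    gs = ref.c_to_genomic(v.start)
    ge = ref.c_to_genomic(v.span_end)
    q = dict(chrom=ref.chrom, depth=20, map_quality=50.0, call_quality=120.0,
             genotype_class=HOMOZYGOUS)
    if v.kind == SUBSTITUTION:
        if v.ref_base != g[gs - 1]:
            raise ValueError(f"reference mismatch at c.{v.start}")
        return VariantRecord(pos=gs, ref=g[gs - 1], alt=v.insert, **q)
    if v.kind == DELETION:
        anchor = g[gs - 2]
        return VariantRecord(pos=gs - 1, ref=anchor + g[gs - 1 : ge], alt=anchor, **q)
    if v.kind == INSERTION:
        return VariantRecord(pos=gs, ref=g[gs - 1], alt=g[gs - 1] + v.insert, **q)
    if v.kind == DUPLICATION:
        return VariantRecord(pos=ge, ref=g[ge - 1], alt=g[ge - 1] + g[gs - 1 : ge], **q)
    if v.kind == INVERSION:
        span = g[gs - 1 : ge]
        return VariantRecord(pos=gs, ref=span, alt=revcomp(span), **q)
    if v.kind == DELINS:
        if v.insert is None:
            raise ValueError("cannot plant a delins with an unfetched external insert")
        anchor = g[gs - 2]
        return VariantRecord(pos=gs - 1, ref=anchor + g[gs - 1 : ge], alt=anchor + v.insert, **q)
    raise AssertionError(v.kind)


def plant_mutations(
    ref: ReferenceBundle,
    specs: Sequence[Sequence[HgvsVariant]] | dict[str, Sequence[HgvsVariant]],
    n_shared: int = 10,
    n_noise: int = 5,
    seed: int = 0,
) -> list[StrainTruth]:
    """Build one call set per strain: planted private mutations (one strain
    each), parental variants identical in every strain with qualities above
    all filter thresholds, and per-strain noise variants each failing at
    least one threshold."""
    if isinstance(specs, dict):
        names = list(specs.keys())
        per_strain = [list(specs[n]) for n in names]
    else:
        per_strain = [list(s) for s in specs]
        names = [f"strain{i + 1:02d}" for i in range(len(per_strain))]
    if not per_strain:
        raise ValueError("at least one strain spec is required")

    cds = ref.cds_model()
    private_records: list[tuple[VariantRecord, ...]] = []
    blocked: set[int] = set()
    for muts in per_strain:
        recs = []
        for v in muts:
            apply_variant(cds, v)  # validates span and reference bases
            r = variant_to_record(ref, v)
            recs.append(r)
            blocked.update(range(r.pos - 1, r.pos + len(r.ref) + 1))
        private_records.append(tuple(recs))

    seen_private = [r.key for recs in private_records for r in recs]
    if len(set(seen_private)) != len(seen_private):
        raise ValueError("private mutations must be unique to one strain each")

    rng = substream(seed, "callsets")
    n_strains = len(per_strain)
    n_positions = n_shared + n_noise * n_strains
    candidates = rng.permutation(np.arange(2, len(ref.genome)))  # keep pos 1 as anchor slack
    pool = [int(p) for p in candidates if p not in blocked][:n_positions]
    if len(pool) < n_positions:
        raise ValueError("genome too small for the requested variant counts")

    shared = tuple(
        _snv(
            ref.genome, pool[i], rng,
            chrom=ref.chrom,
            depth=int(rng.integers(15, 26)),
            map_quality=float(rng.uniform(40, 60)),
            call_quality=float(rng.uniform(60, 200)),
            genotype_class=HOMOZYGOUS,
        )
        for i in range(n_shared)
    )

    truths = []
    cursor = n_shared
    for name, muts, recs in zip(names, per_strain, private_records):
        noise = []
        for k in range(n_noise):
            pos = pool[cursor]
            cursor += 1
            mode = rng.integers(0, 4)
            quality = dict(
                depth=int(rng.integers(10, 30)),
                map_quality=float(rng.uniform(30, 60)),
                call_quality=float(rng.uniform(40, 150)),
                genotype_class=HOMOZYGOUS,
            )
            if mode == 0:
                quality["depth"] = int(rng.integers(0, 4))  # <= 3
            elif mode == 1:
                quality["map_quality"] = float(rng.uniform(0, 20))
            elif mode == 2:
                quality["call_quality"] = float(rng.uniform(0, 20))
            else:
                quality["genotype_class"] = HETEROZYGOUS
            noise.append(_snv(ref.genome, pos, rng, chrom=ref.chrom, **quality))
        truths.append(
            StrainTruth(
                strain_id=name,
                private_mutations=tuple(muts),
                private_records=recs,
                shared_parental_variants=shared,
                noise_variants=tuple(noise),
            )
        )
    return truths


# ---------------------------------------------------------------------------
# depth tracks


def simulate_depth(
    ref: ReferenceBundle | int,
    duplications: Sequence[tuple[int, int]] = (),
    mean_depth: float = 20.0,
    seed: int = 0,
    dispersion: Optional[float] = None,
    chrom: Optional[str] = None,
) -> DepthTrack:
    """Per-position depth drawn from Poisson(mean_depth), doubled inside the
    planted duplication intervals (1-based, inclusive, non-overlapping).

    ``dispersion`` switches to a negative-binomial (gamma-Poisson) model with
    that shape parameter for overdispersed coverage.
    """
    if mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    if isinstance(ref, ReferenceBundle):
        length = len(ref.genome)
        chrom = chrom or ref.chrom
    else:
        length = int(ref)
        chrom = chrom or "chr1"
    intervals = sorted(tuple(d) for d in duplications)
    prev_end = 0
    for s, e in intervals:
        if not 1 <= s <= e <= length:
            raise ValueError(f"duplication ({s}, {e}) outside the genome")
        if s <= prev_end:
            raise ValueError("duplication intervals overlap")
        prev_end = e

    lam = np.full(length, float(mean_depth))
    for s, e in intervals:
        lam[s - 1 : e] *= 2.0
    rng = substream(seed, "depth")
    if dispersion is None:
        depths = rng.poisson(lam)
    else:
        if dispersion <= 0:
            raise ValueError("dispersion must be positive")
        depths = rng.poisson(rng.gamma(dispersion, lam / dispersion))
    return DepthTrack(chrom, depths.astype(np.int64))


# ---------------------------------------------------------------------------
# proteins


def mutate_protein(
    protein: str,
    sub_rate: float = 0.1,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> str:
    """Per-site substitutions (always to a different residue) plus optional
    indels (deletion or single-residue insertion, equal odds)."""
    if not protein:
        raise ValueError("protein must be non-empty")
    if not (0 <= sub_rate <= 1 and 0 <= indel_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = substream(seed, "protein")
    out = []
    for res in protein:
        site = res
        if rng.random() < sub_rate:
            choices = [a for a in AA20 if a != res.upper()]
            site = str(rng.choice(choices))
        if indel_rate and rng.random() < indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(str(rng.choice(list(AA20))))  # insertion before site
        out.append(site)
    return "".join(out)


# ---------------------------------------------------------------------------
# cell images


@dataclass(frozen=True)
class EllipseCell:
    center_x: float
    center_y: float
    radius_x: float
    radius_y: float

    def __post_init__(self):
        if self.radius_x < 3 or self.radius_y < 3:
            raise ValueError("cell radii must be at least 3 px")


@dataclass(frozen=True)
class SyntheticImageSpec:
    image_size: int = 256
    cell: EllipseCell = field(default_factory=lambda: EllipseCell(128, 128, 60, 45))
    cytosol_mean: float = 100.0
    cytosol_sd: float = 10.0
    membrane_mean: float = 100.0
    patch_fraction: float = 0.0
    patch_gain: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.patch_fraction <= 1:
            raise ValueError("patch fraction must lie in [0, 1]")
        if self.patch_gain < 0:
            raise ValueError("patch gain must be >= 0")
        if min(self.cytosol_mean, self.cytosol_sd, self.membrane_mean) < 0:
            raise ValueError("intensities must be >= 0")
        c = self.cell
        if (
            c.center_x - c.radius_x < 1
            or c.center_y - c.radius_y < 1
            or c.center_x + c.radius_x > self.image_size - 2
            or c.center_y + c.radius_y > self.image_size - 2
        ):
            raise ValueError("cell ellipse does not fit inside the image")


def _ellipse_ring_pixels(cell: EllipseCell) -> np.ndarray:
    """Rasterised boundary of the ellipse as an ordered counter-clockwise
    pixel polygon (consecutive duplicates removed)."""
    n = max(int(16 * max(cell.radius_x, cell.radius_y)), 64)
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    xs = np.rint(cell.center_x + cell.radius_x * np.cos(theta)).astype(int)
    ys = np.rint(cell.center_y + cell.radius_y * np.sin(theta)).astype(int)
    pts = np.column_stack([xs, ys])
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
    pts = pts[keep]
    if np.array_equal(pts[0], pts[-1]):
        pts = pts[:-1]
    return pts


def render_cells(
    spec: SyntheticImageSpec,
) -> tuple[np.ndarray, CellOutline, float]:
    """Render one synthetic cell.

    Interior pixels are Normal(cytosol_mean, cytosol_sd) truncated at zero, a
    one-pixel membrane ring sits at membrane_mean, and one contiguous
    perimeter arc covering ``patch_fraction`` of the ring's arc length is
    raised by ``patch_gain``.  Returns (image, outline, planted fraction).
    """
    from skimage.draw import polygon as draw_polygon

    rng = substream(spec.seed, "image")
    ring = _ellipse_ring_pixels(spec.cell)
    outline = CellOutline(ring.astype(float))
    ring = outline.vertices.astype(int)  # CCW-ordered

    img = np.zeros((spec.image_size, spec.image_size), dtype=float)

    rr, cc = draw_polygon(ring[:, 1], ring[:, 0], img.shape)
    interior = np.zeros_like(img, dtype=bool)
    interior[rr, cc] = True
    interior[ring[:, 1], ring[:, 0]] = False
    n_inside = int(interior.sum())
    img[interior] = np.clip(
        rng.normal(spec.cytosol_mean, spec.cytosol_sd, size=n_inside), 0, None
    )

    img[ring[:, 1], ring[:, 0]] = spec.membrane_mean

    # patch: a contiguous arc-length window on the ring polygon
    seg = np.linalg.norm(np.diff(np.vstack([ring, ring[:1]]), axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg[:-1])])  # arc position of each vertex
    perimeter = float(seg.sum())
    if spec.patch_fraction > 0:
        start = float(rng.uniform(0, perimeter))
        span = spec.patch_fraction * perimeter
        rel = (arc - start) % perimeter
        in_patch = rel < span if spec.patch_fraction < 1 else np.ones(len(arc), bool)
        img[ring[in_patch, 1], ring[in_patch, 0]] += spec.patch_gain

    return img, outline, spec.patch_fraction
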