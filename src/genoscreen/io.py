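"""Readers and writers for the plain-text interchange formats used by the
pipeline: a VCF v4.2 subset, 3-column depth TSVs, FASTA, grayscale images and
outline polygons as JSON."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .triage import HETEROZYGOUS, HOMOZYGOUS, StrainCallSet, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_depth_tsv",
    "read_depth_tsv",
    "write_fasta",
    "read_fasta",
    "write_image",
    "read_image",
    "write_outline_json",
    "read_outline_json",
]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf(calls: StrainCallSet, path: str | Path) -> None:
    """Write a call set as an uncompressed VCF v4.2 subset (haploid GT)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_VCF_HEADER.format(sample=calls.strain_id))
        for r in calls.records:
            gt = "1" if r.genotype_class == HOMOZYGOUS else "0/1"
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{r.call_quality:g}\t.\t"
                f"DP={r.depth};MQ={r.map_quality:g}\tGT\t{gt}\n"
            )


def _genotype_class(gt: str) -> str:
    alleles = {a for a in gt.replace("|", "/").split("/") if a != "."}
    return HOMOZYGOUS if len(alleles) == 1 and alleles != {"0"} else HETEROZYGOUS


def read_vcf(path: str | Path, strain_id: str | None = None) -> StrainCallSet:
    """Read the VCF subset written by :func:`write_vcf` (or any VCF carrying
    QUAL, INFO/DP, INFO/MQ and a single sample GT).  Multi-allelic lines are
    split into one record per ALT.  Malformed lines are skipped with a
    warning tally rather than aborting the run."""
    path = Path(path)
    records: list[VariantRecord] = []
    sample = None
    n_bad = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                sample = cols[9] if len(cols) > 9 else None
                continue
            try:
                records.extend(_parse_vcf_line(line))
            except Exception as exc:  # noqa: BLE001 - tally and continue
                n_bad += 1
                logger.warning("%s line %d: skipping malformed record (%s)", path, lineno, exc)
    if n_bad:
        logger.warning("%s: %d malformed record(s) skipped", path, n_bad)
    return StrainCallSet(strain_id or sample or path.stem, tuple(records))


def _parse_vcf_line(line: str) -> list[VariantRecord]:
    cols = line.split("\t")
    chrom, pos, _id, ref, alts, qual = cols[0], int(cols[1]), cols[2], cols[3], cols[4], cols[5]
    info = dict(
        kv.split("=", 1) if "=" in kv else (kv, "1") for kv in cols[7].split(";") if kv and kv != "."
    )
    depth = int(float(info.get("DP", 0)))
    mq = float(info.get("MQ", 0.0))
    gt = "1"
    if len(cols) > 9:
        fmt = cols[8].split(":")
        vals = cols[9].split(":")
        if "GT" in fmt:
            gt = vals[fmt.index("GT")]
    out = []
    for alt in alts.split(","):
        if alt in (".", "<NON_REF>", "*"):
            continue
        out.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                depth=depth,
                map_quality=mq,
                call_quality=float(qual) if qual != "." else 0.0,
                genotype_class=_genotype_class(gt),
            )
        )
    return out


def write_depth_tsv(chrom: str, depths: np.ndarray, path: str | Path) -> None:
    """3-column depth track: chrom, 1-based position, integer depth."""
    df = pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(1, len(depths) + 1), "depth": np.asarray(depths, dtype=int)}
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_depth_tsv(path: str | Path) -> tuple[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "depth"])
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(f"expected one chromosome per depth track, got {list(chroms)}")
    df = df.sort_values("pos")
    pos = df["pos"].to_numpy()
    if not np.array_equal(pos, np.arange(1, len(pos) + 1)):
        raise ValueError("depth track positions must be contiguous from 1")
    return str(chroms[0]), df["depth"].to_numpy(dtype=np.int64)


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()],
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a 2-D intensity grid as 16-bit grayscale TIFF or PNG."""
    path = Path(path)
    arr = np.clip(np.rint(np.asarray(image, dtype=float)), 0, 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), arr)
    else:
        from PIL import Image

        Image.fromarray(arr).save(str(path))


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(str(path)).astype(float)
    from PIL import Image

    return np.asarray(Image.open(str(path)), dtype=float)


def write_outline_json(vertices: np.ndarray, path: str | Path) -> None:
    """Outline polygon as a JSON list of [x, y] pixel vertices (origin
    top-left, x rightward, y downward)."""
    data = [[float(x), float(y)] for x, y in np.asarray(vertices)]
    Path(path).write_text(json.dumps(data))


def read_outline_json(path: str | Path) -> np.ndarray:
    return np.asarray(json.loads(Path(path).read_text()), dtype=float)
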