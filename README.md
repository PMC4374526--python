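# genoscreen

Analysis toolkit for causal-mutation discovery in forward genetic screens of
a haploid microbe, with synthetic-data generators for end-to-end testing.
It covers five stages:

- **variant triage** — quality pre-filtering of per-strain variant calls
  (depth > 3, mapping quality > 20, call quality > 20, heterozygous-class
  calls dropped; all strict), subtraction of variants common to every strain
  (parental differences from the reference), and coding-region flagging.
- **effect annotation** — an HGVS c.-notation parser (substitution, deletion,
  insertion, duplication, delins incl. external-accession inserts,
  inversion), variant application to a CDS, consequence classification
  (frameshift / nonsense / missense / silent / in-frame classes / start-lost /
  upstream), and a 3'-normalising variant namer.
- **depth CNV scan** — rolling-median smoothing (window 999), subsampling
  every 1000th position, and calling of contiguous runs at roughly double the
  background median as duplication segments with copy-ratio estimates.
- **homology profiling** — in-house affine-gap Smith–Waterman and
  Needleman–Wunsch (BLOSUM62, gap open 10, extend 0.5 by default), sliding
  200-residue window profiles normalised to per-window self scores, global
  %identity/%similarity with gap columns counted, and query→target position
  mapping through a global alignment.
- **membrane patch quantification** — equidistant perimeter resampling of a
  cell outline polygon (2 px), max intensity along 3-px normals, cytosol
  statistics from the eroded interior, and the fraction of perimeter points
  above cytosol mean + 3 SD.

The `synthetic` module generates every input with known ground truth:
reference genomes with an embedded CDS, strain call sets with planted
private/shared/noise variants, Poisson depth tracks with planted tandem
duplications, diverged proteins, and cell images with planted membrane
patches.

## CLI

Installed as `genoscreen` (equivalently `python -m genoscreen.cli`):

```sh
# synthetic inputs (stochastic stages require --seed)
genoscreen simulate strains --n-strains 4 --seed 7 --out-dir sim/
genoscreen simulate depth --length 2000000 --duplication 1200001:1500000 --seed 7 --out depth.tsv
genoscreen simulate proteins --length 400 --seed 7 --out prot.fa
genoscreen simulate cells --patch-fraction 0.25 --seed 7 --out-dir cells/

# analyses
genoscreen triage --vcf sim/strain01.vcf --vcf sim/strain02.vcf \
    --vcf sim/strain03.vcf --vcf sim/strain04.vcf \
    --cds chr1:2001-2300 --out-dir triage/
genoscreen annotate --cds cds.fa --variants variants.tsv --out effects.tsv
genoscreen cnv-scan --depth-tsv depth.tsv --out-dir cnv/
genoscreen homology --fasta prot.fa --out-dir hom/
genoscreen patches --image cells/cell.tif --outline cells/cell_outline.json --out-dir patches/
```

All file formats are plain text (VCF v4.2 subset, 3-column depth TSV, FASTA,
outline JSON) except images (16-bit grayscale TIFF/PNG).

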