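# thetascan

Discovery-and-validation toolkit for tRNA-processing HDV-like ("theta")
ribozymes in phage-like genome sequences:

* **Structural motif search** — a line-based descriptor language for ordered
  structural elements (single strands and helix strands that may interleave,
  so pseudoknots are expressible), IUPAC identity constraints, G–T wobble
  pairing, and an ambiguous-nucleotide budget (`nratio`). Both genome strands
  are scanned. Three catalytically substituted false-positive motifs
  (C→A/G/U at the first J4/2 position) are derived automatically; a locus
  matching both the active and a substituted motif counts as a true positive.
* **tRNA association** — a ribozyme is tRNA-associated when a tRNA 3′ end
  lies within ±5 nt of the cleavage site (same contig and strand). Records
  carry signed distances, direct (|d| ≤ 1) / near (2–5 nt) adjacency classes,
  suppressor-anticodon and CCA-tail flags, occurrence-ranked pair names
  (`tRNAVal0025_Θ0046`), and genomic-context labels for isolated hits
  (intragenic / sense / antisense / distal at > 200 nt).
* **Genetic-code assignment** — six-frame maximal ORFs under codes 11, 15
  (TAG→Gln) and 4 (TGA→Trp); a contig is recoded when the alternative-code
  coding density exceeds the standard-code density by 10 % (contigs < 100 kbp)
  or 5 % (≥ 100 kbp).
* **Self-scission kinetics** — cleaved fractions from cytosine-corrected band
  intensities, inverted mono-/biexponential fits (k_obs = faster rate for
  biexponential), Hill-type Mg²⁺ dependence, and the two-pKa pH-rate profile,
  plus trace simulators for parameter-recovery testing.
* **Synthetic data** — seeded phage-like contigs with embedded motif
  instances, tRNA cassettes at defined spacings, code-11/15 ORFs with
  controlled in-frame TAG rates, read sampling, and a ground-truth manifest,
  so the whole pipeline is testable offline.

Two descriptors are shipped in `src/thetascan/data/`: `minimal_drz.desc`
(a loose minimal motif that matches the published drz-Mtgn-1 sequence) and
`theta_final.desc` (the refined motif with tighter constraints and a
degenerate final J4/2 position; used by default and by the generator).

## CLI

```sh
thetascan simulate --out-dir demo --seed 1 --n-contigs 4 --length 6000
thetascan scan      --fasta demo/contigs.fasta --out-dir demo/scan
thetascan associate --hits demo/scan/hits.tsv --trna demo/trna.tsv \
                    --fasta demo/contigs.fasta --out-dir demo/assoc
thetascan recode    --fasta demo/contigs.fasta \
                    --associations demo/assoc/associations.tsv \
                    --hits demo/scan/hits.tsv --out-dir demo/recode
thetascan fit       --data kinetics.tsv --out-dir demo/fit
```

Stages read/write plain-text formats (FASTA, GFF3, TSV, JSON) and are
deterministic for fixed seeds. Kinetics tables need columns `time_min`,
`replicate`, and either `f` or `I_tRNA`/`I_substrate`, with optional
`condition_type` (`mg` or `ph`) and `condition_value` to trigger Hill/pH
fits across conditions.

## Notes

* ORF calling is a deterministic maximal-ORF surrogate (starts ATG/GTG/TTG,
  default min length 90 nt), not a gene finder. At 90 nt the six-frame ORF
  union saturates on random DNA, so tests that probe *partial* density
  excesses use a 450 nt minimum ORF where the density-difference statistic
  is informative; fully recoded genomes are detected at the default.
* Descriptor dialect, distance sign conventions and tie-breaking rules are
  documented in the module docstrings (`motif_engine`, `trna_annotate`).
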