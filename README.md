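# fxivar

Structural and census analysis of genetic variants in coagulation
**Factor XI** (the *F11* gene).

FXI is a 625-residue plasma serine-protease zymogen (an 18-residue
signal peptide, four homologous Apple domains Ap1–Ap4 and a serine
protease domain) that circulates as a disulfide-linked dimer. Variants
that destabilise its tightly packed domain structure cause FXI
deficiency, a bleeding disorder. Clinically, **Type I** (CRM⁻) variants
depress both coagulant activity (FXI:C) and antigen (FXI:Ag) — typically
misfolding followed by degradation — while **Type II** (CRM⁺) variants
depress activity with normal antigen, operationally a FXI:C/FXI:Ag
ratio < 0.7.

This package implements, as a reusable library plus CLI, the analyses a
curated FXI variant database is built on:

- **Variant census** (`fxivar.census`) — HGVS protein-change parsing
  (`Cys56Arg`, `Glu135*`, slashed shorthand `Cys56Arg/Trp`), HGVS ↔
  legacy (mature-protein) numbering with its fixed offset of 18,
  activity/antigen phenotype classification, allele-frequency rarity
  filtering, and tabulation by event type, effect, phenotype and domain.
- **Substitution metrics** (`fxivar.substitution`) — single-nucleotide
  reachability under the standard genetic code, the 20×20 missense
  substitution grid, and the Grantham amino-acid distance built from
  first principles:

  D(i,j) = ρ·[α(cᵢ−cⱼ)² + β(pᵢ−pⱼ)² + γ(vᵢ−vⱼ)²]^½

  with α = 1.833, β = 0.1018, γ = 0.000399 and ρ normalising the mean
  over the 190 unordered pairs to 100. Rounded to integers this spans 5
  (Leu–Ile) to 215 (Cys–Trp); identical residues score 0.
- **Solvent accessibility** (`fxivar.accessibility`) — deterministic
  golden-spiral sphere-sampling SASA, conversion to percent of a
  theoretical maximum sidechain area, decile binning (0–9% → bin 0,
  10–19% → bin 1, …) and buried (bins 0–1) vs exposed (bins 2–9)
  classification, with phenotype × burial cross-tabulation of variants.
- **Domain partition** (`fxivar.partition`) — accessibility changes when
  the protein is cut into its five domains (interdomain contacts),
  per-residue buried surface area of multi-chain assemblies (dimer
  interface at BSA > 5 Å²), geometric disulfide detection (Sγ–Sγ ≤
  2.3 Å) and rigid-body dimer assembly.
- **Consensus Apple domain** (`fxivar.consensus`) — alignment of
  Ap1–Ap4 anchored on their six conserved cysteines (C1..C6), and
  projection of Apple-domain variants onto consensus columns.
- **Synthetic data** (`fxivar.synthetic`) — toy helices, packed pairs
  with designed interfaces, disulfide scaffolds and marginal-exact
  synthetic censuses, so every stage is testable offline.

The bundled census fixture transcribes the printed variant lists and
tallies of the curated database (272 variants, 154 missense among 200
point variants, 96 Type I of 227 disease-associated, 28 Cys-loss and 13
Cys-gain variants, gnomAD allele-frequency strata); rows without printed
per-variant detail are aggregate rows (`aggregate=true`). The bundled
FXI FASTA is a **synthetic stand-in** sequence (see its header and
`docs/methods.md`): all residue identities the analyses depend on are
fixed, the rest is filler.

## Worked example

```bash
$ fxivar census --census src/fxivar/data/fxi_census.csv --out-dir reports
272 variants (227 disease-associated); AF>0.01: 9 common, 108 rare, 155 without AF
Cys variants: 28 loss (20 Apple, 8 SP), 13 gain
```

272 unique variants, of which 227 are disease-associated and 45 are
non-disease polymorphisms; of the 117 with a gnomAD allele frequency,
only 9 exceed the 0.01 common-variant cutoff (all polymorphisms). The
census counts 28 distinct variants that remove a native cysteine (20 in
the Apple domains, 8 in the protease domain) and 13 that introduce one —
every one reachable by a single nucleotide change. The written
`reports/census_summary.tsv` starts:

```
grouping     category      count  percent
event_type   point         200    73.53
event_type   polymorphism  45     16.54
event_type   deletion      19     6.99
```

From Python:

```python
>>> from fxivar import parse_protein_change, hgvs_to_legacy, grantham_distance
>>> parse_protein_change("Phe301Leu")
('Phe', 301, 'Leu', <Effect.MISSENSE: 'missense'>)
>>> hgvs_to_legacy(301)          # mature-protein numbering
283
>>> grantham_distance("Phe", "Leu")   # conservative exchange
22
>>> grantham_distance("Cys", "Arg")   # radical exchange
180
```

Other subcommands: `grid` (substitution grid), `grantham`, `sasa`
(accessibility profile from a PDB/mmCIF file), `separate`
(domain-separation deltas), `interface` (dimer BSA), `disulfide`,
`consensus`, `simulate` (synthetic toys). Run `fxivar COMMAND --help`
for flags (`--probe-radius`, `--n-points`, `--bsa-cutoff`,
`--af-cutoff`, `--domain-map`, `--seed`, `--out-dir`).

To analyse the real zymogen crystal structure, download PDB entry 6I58
and pass it to `sasa` / `separate` / `disulfide`; nothing in the test
suite requires it.

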