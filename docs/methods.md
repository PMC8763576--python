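# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `fxivar`. It describes what the code computes; every
number quoted here is produced by the test suite or the acceptance
script, not asserted from memory.

## Variant census model

A variant is one record: protein change in HGVS notation (three-letter
codes, `*`/`Ter` for stop), event type (point, deletion, insertion,
duplication, polymorphism, undefined), effect (missense, nonsense,
silent, undefined), phenotype (Type I, Type II, unknown, polymorphism),
optional FXI:C / FXI:Ag levels (IU/dL), optional gnomAD allele
frequency, and pass-through external scores (PolyPhen-2, SIFT, PROVEAN,
Grantham) that this package stores but never recomputes (except
Grantham, which it derives itself).

Numbering. HGVS protein numbering starts at the initiator Met of the
18-residue signal peptide; "legacy" numbering starts at the first mature
residue (Glu19), so `legacy = hgvs − 18`, valid for residues 19–625
(607 mature residues + 18 signal). Signal-peptide residues have no
legacy equivalent and conversion raises an explicit error.

Phenotype rule. FXI:C within the 70–150 IU/dL normal range →
unaffected. Below it, FXI:C/FXI:Ag < 0.7 → Type II (functional defect,
CRM⁺), otherwise Type I (parallel protein loss, CRM⁻). Missing antigen
→ unknown. Records are polymorphisms only when labelled so in the
source; allele frequency never reclassifies a record.

Tabulation denominators mirror the database reports: event types over
all variants, effects over point variants only, phenotypes over
disease-associated variants (everything that is not a polymorphism),
domains over all variants. Percentages are rounded half-up to 2 d.p.
(1 d.p. for the phenotype split, matching the printed precision).

Aggregate rows. The bundled census (`data/fxi_census.csv`) transcribes
every variant the literature names individually (the cysteine lists,
the recurrent variants, hotspot and interface positions) as per-variant
rows, and carries the remaining printed marginal counts as rows with
`aggregate=true` and a `count`. Tabulation and rarity filtering weight
aggregate rows by their count; per-variant analyses (grids, projections,
cysteine census) use only the non-aggregate rows. The phenotype-by-
effect split inside the aggregate block is not printed anywhere; it was
chosen once to be simultaneously consistent with all printed marginals
and is not otherwise meaningful.

Domain map. Default intervals: signal 1–18, Ap1 19–108, Ap2 109–198,
Ap3 199–288, Ap4 289–379, SP 380–625. Exact printed boundaries are not
available in the transcribed text; these bracket the published
disulfide spans of each domain and the Arg387–Ile388 activation site.
The map is a plain value object and fully configurable; analyses that
depend only on the Ap4/SP split are insensitive to its placement within
375–415. The single 31.5 kb deletion spanning several domains carries
no residue position and tabulates as domain `undefined`.

## Substitution metrics

Reachability. The standard nuclear genetic code is hard-coded;
`single_nt_reachable(a, b)` holds iff some codon of `a` differs from
some codon of `b` in exactly one position. Stop codons participate (for
nonsense variants) but never enter the 20×20 grid. Identity is treated
as reachable by convention (synonymous identity); silent changes are
excluded from the grid regardless. The test suite checks the function
against a brute-force enumeration over all codon pairs.

Grid. Each *distinct* missense protein change increments one (ref, alt)
cell. A change landing in a cell not reachable by a single nucleotide
substitution is flagged as suspect and warned about but still counted —
census entries are trusted over the filter.

Grantham distance. D(i,j) = ρ·[α(cᵢ−cⱼ)² + β(pᵢ−pⱼ)² + γ(vᵢ−vⱼ)²]^½
over the 1974 composition (c), polarity (p) and molecular-volume (v)
table bundled as `data/grantham_properties.csv`, with α = 1.833,
β = 0.1018, γ = 0.000399. ρ is not stored: it is derived at run time so
that the mean over the 190 unordered pairs equals 100. Scores are
rounded to the nearest integer, reproducing the conventional published
matrix (minimum non-trivial distance 5 for Leu–Ile, maximum 215 for
Cys–Trp, e.g. Arg–Leu 102). Stop codons have no defined distance and
raise.

## Solvent accessibility

Algorithm. A deterministic variant of sphere-point sampling: each
atom's solvent-expanded sphere (van der Waals radius + probe, probe
default 1.4 Å) is covered with a golden-section spiral lattice of
`n_points` points (default 960) and a point is accessible iff it lies
outside every neighbouring expanded sphere. Atomic SASA = accessible
fraction × expanded-sphere area. The spiral lattice makes results
exactly reproducible with no seed; neighbour search uses a k-d tree.
Coincident atom centres are rejected. Choosing the point count trades
accuracy for time; at 960 points per-residue values agree with a
10,000-point run within 2% on the toys, and with an independent
implementation (biotite's Shrake–Rupley) within the same tolerance.

Radii. Fixed element radii: C 1.70, N 1.55, O 1.52, S 1.80, P 1.80,
Se 1.90 Å. Hydrogens are dropped on reading; an element without a
configured radius is an error rather than a guess.

Percent and bins. Per-residue *sidechain* SASA (Gly: the Cα stands in
as the sidechain, a DSSP-style convention) is divided by a theoretical
maximum sidechain area per residue type. The bundled table
(`data/max_asa_sidechain.csv`) is a Gly-X-Gly tripeptide-scale set;
because the downstream analysis uses decile bins, bin boundaries — not
absolute maxima — carry the signal, and the table is replaceable via a
plain dict argument. Percent > 100 can occur in extended conformations;
the bin is capped at 9. Bins: floor(percent/10), buried ⇔ bin ≤ 1.
Residues missing from the structure or absent from the max table are
reported as "not classified", never silently dropped.

Secondary structure is out of scope: a reader for classic DSSP output
is provided for importing third-party accessibilities/assignments, but
the eight-state algorithm is never computed here.

## Domain separation and interfaces

Separation delta. Accessibility is computed for the intact structure
and for each isolated domain; delta = bin(isolated) − bin(intact).
Because the same lattice is used and isolation only removes occluding
atoms, per-atom accessible counts are monotone and delta ≥ 0 for every
residue — asserted on every run, not just tested. Residues with
delta ≥ 1 bin (10 percentage points) are reported as interdomain
contacts.

Interface BSA. Per-residue buried surface area = SASA(residue, own
chain alone) − SASA(residue, assembly), over all atoms of the residue;
the interface set is BSA > 5 Å² by default. On symmetric toy dimers the
per-chain interface sets are identical and the summed per-residue BSA
matches the total SASA loss within sampling tolerance.

Disulfides. Cys Sγ pairs within 2.3 Å (covalent ≈ 2.05 Å; the margin
tolerates refinement noise while excluding van der Waals contacts),
resolved greedily nearest-first so each Cys joins at most one bridge;
interchain pairs are flagged, unpaired Cys are listed as free.

Dimer assembly. A rigid-body transform (rotation + translation) applied
to a copy of the monomer; the only safety check is a minimum
interatomic distance warning (< 1 Å) that catches identity-like
transforms. No interface-significance or free-energy estimation is
attempted (that was the job of the PISA-class tools this package does
not replace), and for the real dimer the crystallographic two-fold
should be supplied as configuration rather than discovered.

Salt bridges. A demo-level distance screen (basic sidechain N to acidic
sidechain O ≤ 4 Å), provided for inspecting the dimer's Glu305–Lys349
and Asp307–Arg363 pairings on real coordinates.

## Consensus Apple domain

The four Apple domains each contain six conserved cysteines forming the
C1–C6, C2–C5, C3–C4 bridges. The consensus alignment anchors the six
Cys columns a priori (a missing anchor is an error) and aligns the
seven inter-anchor segments independently by global pairwise alignment
(BLOSUM62, gap open −10, extend −0.5, configurable) merged center-star
around the longest segment. This replaces the structural superposition
used for the original database: anchor columns are identical by
construction, but inter-anchor gap placement — and hence consensus
length — may differ, so the column count is reported, never asserted.
With identical input sequences the alignment reduces exactly to the
identity mapping. Projection counts each distinct missense change
(disease or polymorphism) once in its column; the dominant phenotype of
a column is the modal phenotype, ties reported as unknown; variants
outside the mapped domains are returned, not discarded.

## Synthetic data: what it emulates, what it does not

The generators exist so that every stage runs and is testable with
known ground truth and no downloads:

- `make_helix` — ideal α-helix (rise 1.5 Å, 100°/residue, Cα radius
  2.3 Å) with approximate backbone geometry and one pseudo-sidechain
  sphere (C radius 1.9 Å, extended 2.0 Å radially) per non-Gly residue.
  This is deliberately not biophysical: no rotamers, no real sidechain
  shapes. It provides controllable exposure.
- `make_packed_pair` — two helices packed face to face with a
  controlled surface gap; the designed contact set (pseudo-sidechain
  surfaces within gap + 2 Å of the partner, capped at one probe
  diameter, beyond which no burial is geometrically possible) is
  emitted as ground truth and is recovered exactly by the interface
  analysis at the default cutoffs.
- `make_disulfide_scaffold` — encodes any bridge topology as real
  geometry (Sγ pairs at 2.05 Å in well-separated cells), so the
  disulfide census of the monomer (17 bridges, free Cys29) and of the
  dimer (the interchain Cys339–Cys339) is always detected from
  coordinates, never read off a list.
- `make_census` — synthetic censuses whose tabulation reproduces the
  requested marginals exactly; protein changes are distinct and respect
  single-nucleotide reachability. Deterministic under a fixed seed.

Consequently, passing structure tests demonstrates the correctness of
the geometry and bookkeeping, not agreement with the crystal structure
of the zymogen: analyses of the real molecule require downloading PDB
entry 6I58 and supplying the crystallographic two-fold for the dimer.
Burial statistics quoted for the real structure in the literature (e.g.
the Type I burial majority) are therefore exercised here only as
directional properties on synthetic stand-ins.

The bundled FXI sequence is likewise a synthetic stand-in (the header
says so): the 625-residue frame, the full cysteine topology, catalytic
triad, activation site and all named variant/interface residue
identities are fixed; filler positions exclude Cys so the disulfide
census stays exact. Alignment tests against it check anchor and column
structure, not real inter-anchor homology.

## Numerical and interface choices

- Percent rounding is half-up (`Decimal`), matching printed tallies;
  floating-point bankers' rounding would disagree at exact .5 ties.
- SASA point counts below 100 are refused; sampling error grows
  quickly there.
- The census CSV schema is fixed (see `fxivar.census.CENSUS_COLUMNS`);
  malformed rows fail loudly with the row number and offending token.
- CLI reports embed the tool version and input SHA-256; identical
  inputs give byte-identical reports.
- Problem sizes in the test suite (12-residue helices, 960/10,000
  sample points, the 272-record fixture) were chosen as the smallest
  sizes at which the analytic ground truths are non-trivial.

## Known limitations

- PolyPhen-2/SIFT/PROVEAN are pass-through annotations only.
- The theoretical max-ASA table choice shifts absolute percent values;
  per-residue bins on real structures should not be compared across
  different tables.
- PISA-style interface areas and the sphere-sampling BSA can disagree
  near the 5 Å² boundary; reproducing a published interface list to the
  residue is best-effort.
- The center-star segment merge is optimal pairwise, not jointly; with
  highly divergent inter-anchor segments the consensus can be longer
  than a structure-based alignment would give.
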