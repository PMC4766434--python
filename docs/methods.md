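# Methods

## Problem and overall procedure

Classical protein kinase C (cPKC) isoenzymes are autoinhibited: in the
inactive conformation the C2 regulatory domain packs against the catalytic
(kinase) domain and masks their shared interface. Activation releases this
packing, so a peptide that lies *in* the interface is a conformational marker
— buried when the kinase is off, exposed when it is on. An antibody raised
against such a peptide recognizes only the active enzyme. `epistate`
implements the computational arm of this strategy as four stages:

1. **Inactive-model reconstruction.** Deposited crystal structures often
   contain the closed packing only *between* asymmetric units. Starting from
   a PDB file with CRYST1 cell and space-group information, all images of the
   catalytic domain under the space-group operators combined with lattice
   translations in {−1, 0, +1}³ (adjacent cells only) are generated, and
   every image with a heavy atom within the contact shell of the regulatory
   domain is a candidate docking partner. Among contacting images the one
   burying the largest interface area (ΔSASA summed over both sides) is
   selected; the number of residue contacts is logged alongside for
   comparison. The regulatory domain stays in the reference frame and the
   partner image moves; the opposite frame choice is related by a rigid
   motion and changes no distance or area. The inter-domain linker span is
   deleted from the model (it is physically cut when the two domains are
   treated as separate rigid bodies) and must not overlap either domain.
   Ties between equal-area images break by operator index, then lattice
   shift, so the output is deterministic; residues and atoms are
   canonically sorted so it is also independent of input atom order.

2. **Exposure analysis.** Per-residue solvent-accessible surface area is
   computed by the Shrake–Rupley method on a deterministic golden-spiral
   lattice (default 960 points/atom, probe 1.4 Å; per-element radii C 1.70,
   N 1.55, O 1.52, S 1.80 Å; hydrogens excluded everywhere). `sasa_open` is
   the isolated domain, `sasa_closed` the full assembly; their difference
   ΔSASA is the burial caused by the partner, non-negative by construction
   up to 1e-6 numerical tolerance. Relative exposure normalizes `sasa_open`
   by the residue type's Gly-X-Gly maximum (theoretical values of Tien et
   al. 2013), capped at 1.

3. **Conservation and epitope ranking.** Alignment columns (FASTA or
   Clustal; family labels target/off-target supplied by the user) are scored
   by consensus-match fraction within the target family — consensus ties
   break alphabetically, and a gap counts as a mismatch because an indel
   destroys a linear epitope — plus the fraction of off-target sequences
   differing from that consensus. A normalized-entropy alternative is
   available behind a switch. Columns map to structure numbering through a
   reference sequence and offset. Every peptide window (default 15 residues,
   the length of the C2Cat immunogen) is then scored on four components in
   [0, 1]: burial fraction in the closed state (ΔSASA / SASA_open averaged
   over the window), open-state relative exposure, target conservation and
   off-target divergence. The composite is their weighted geometric mean —
   the criteria are conjunctive, so failing any one zeroes the candidate; a
   weighted arithmetic mean is available behind a switch. Ties rank the
   N-terminal-most window first; windows with undefined positions are
   reported in a skipped list, never dropped silently.

4. **IHC quantification.** Stained-tissue images (8-bit grayscale, or RGB
   reduced by ITU-R 601 luminosity) are quantified by positive pixel count:
   with cut points (100, 175, 220) the bands are strong [0,100),
   positive [100,175), weak [175,220] and negative (220,255]. Darker pixels
   carry more chromogen, so the darkest band is the strongest staining; note
   that published figure legends sometimes list the labels in the opposite
   order, which is internally inconsistent with the color coding — this
   package always binds *strong* to the darkest band. The top cut point
   closes the weak band, so intensity 220 is weak; band membership is
   otherwise half-open upward and stated bit-exactly so counts are
   reproducible. Each sample's positivity score is 256 − mean intensity over
   analyzable pixels (the mask, e.g. a pathologist's tumor-area selection,
   restricts the mean); the per-pixel mean is used rather than a per-class
   mean. Cohorts are compared with an unpaired two-sided Student t-test
   (Welch behind a switch); with both variances zero and differing means the
   t statistic is reported as ±infinity with p = 0.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| contact cutoff | 4.5 | Å heavy-atom | standard inter-residue contact convention |
| salt-bridge cutoff | 4.0 | Å, side-chain N(K/R/H)–O(D/E) | standard salt-bridge geometry |
| mate-search shell | = contact cutoff | Å | a mate is relevant iff it can form a contact |
| SASA probe | 1.4 | Å | water probe |
| SASA points | 960 | points/atom | ≲0.5% area error at ~3× the 320-point default of common tools; configurable |
| window length | 15 | residues | length of the C2Cat immunogen peptide |
| component weights | 1,1,1,1 | — | no criterion is privileged a priori |
| pixel cut points | 100, 175, 220 | intensity | the standard positive-pixel-count defaults |

The lattice search is limited to shifts in {−1, 0, +1}³ because a mate
touching the reference copy must come from an adjacent cell; the built-in
operator tables cover all Hermann–Mauguin space groups (via gemmi), and
arbitrary `x,y,z`-style triplets are accepted.

## Synthetic data: what it emulates and what it does not

*Toy crystal* — two short poly-alanine-backbone chains (N, CA, C per
residue; a Lys NZ and a Glu OE1 surrogate on the planted pair) in a P1 cell,
placed so the chains are >20 Å apart in the deposited frame while the −a
lattice translate of the partner chain docks its carboxylate 3.0 Å from the
regulatory chain's ammonium nitrogen. This reproduces the *topology* of the
crystallographic situation — contact exists only through symmetry, exactly
one image contacts, the contact validates as a salt bridge — with minimal
geometry. It does not emulate realistic protein shape, packing density, or
multiple competing interfaces, so passing the planted-recovery tests shows
the search and selection logic is correct, not that the buried-area
criterion discriminates between several plausible mates of a real crystal.

*Toy alignment* — six target and two off-target sequences of length 20, a
planted 5-residue window kept identical across targets, background
substitution probability 0.35 outside the window, off-target substitution
probability 0.8 inside it. This emulates the conserved-in-family /
divergent-in-off-target column pattern; it does not emulate realistic
phylogenetic correlation between sequences or alignment errors. Generation
self-validates that no equal-length window out-scores the planted one.

*IHC cohorts* — 105 ER-positive and 29 triple-negative samples (the
tissue-microarray design), per-sample positivity scores normal(80, 20) for
ER+ and mean-shifted by 1.5 SD for triple-negative, truncated to the valid
(1, 256] score range. The published comparison reports only a p-value bound
(p < 0.0001) at these n, not an effect size; 1.5σ is this package's chosen
default and gives an expected two-sample t of ≈7, so the bound reproduces
robustly across seeds without being knife-edge. Optional per-sample images
encode each score as the pixel mean 256 − score with SD 8, so quantifying an
image recovers its score to within a fraction of an intensity unit. The
generator draws i.i.d. normal scores; it does not emulate staining texture,
spatial correlation, or batch effects.

## Numerical choices and degenerate inputs

- The sphere-point lattice is deterministic, so SASA is bit-reproducible and
  an isolated atom scores exactly 4π(r+probe)²; exposed points are counted
  integrally so the result equals a per-point loop oracle bit-for-bit.
- A structure without CRYST1 parses with an undefined cell and the identity
  operator only; any symmetry operation then raises rather than guessing.
- Alternate locations keep the highest-occupancy conformer; waters are
  dropped; annotation spans tolerate missing (disordered) residues as real
  crystals require, but an annotation matching no residue at all is an
  error.
- Burial fractions treat a residue with zero open-state SASA as 0 (fully
  buried even when isolated, so assembly cannot bury it further).
- Windows containing residue types without a reference exposure area are
  skipped with a reason rather than scored on a guess.
- A no-contact symmetry search returns an explicit no-assembly result with
  the searched-operator count instead of raising.

## Known limitations

- Interface detection is purely geometric; no electrostatics, hydrogen-bond
  geometry or interface energy scoring.
- The epitope composite formalizes criteria the original selection applied
  by expert inspection; on real structures the intended peptide is expected
  near the top of the ranking, not necessarily at rank 1.
- mmCIF input, assembly generation beyond single-domain mates, antigenicity
  prediction and stain color deconvolution are out of scope.
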