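# epistate

Structure-guided selection of **activation-state-specific antibody epitopes**
on multi-domain kinases, plus the positive-pixel immunohistochemistry (IHC)
quantification used to validate such an antibody across tumor cohorts.

## The problem

Classical protein kinase C (cPKC) isoenzymes are autoinhibited: in the
inactive conformation the C2 regulatory domain packs against the catalytic
domain. Phosphorylation marks maturation, not activation, so ordinary
antibodies cannot tell an active kinase from an inactive one in tissue. A
peptide lying in the C2/catalytic interface is buried when the kinase is off
and exposed when it is on — an antibody raised against it reports activation
state. `epistate` is for structural bioinformaticians and antibody designers
who want to select such peptides rationally, and for pathology groups who
need the matching slide quantification.

The pipeline:

1. **Reconstruct the inactive assembly** from a crystal: the closed packing
   often exists only between asymmetric units, so all space-group images of
   the catalytic domain within adjacent unit cells ({−1,0,+1}³ lattice
   shifts) are screened for contact with the C2 domain, and the image
   burying the largest interface area is docked (the inter-domain linker is
   deleted). Expected contacts — e.g. the K205–E655 salt bridge of PKCβ —
   validate the model.
2. **Quantify exposure**: per-residue Shrake–Rupley SASA in the isolated
   (active-like) domain versus the assembly; ΔSASA = SASA_open − SASA_closed
   is the burial each residue suffers in the closed state.
3. **Rank peptide windows** by the weighted geometric mean of four [0,1]
   components: burial in the closed state, exposure in the open state,
   target-family conservation, off-target-family divergence —

   composite = (burial^w1 · exposure^w2 · conservation^w3 · divergence^w4)^(1/Σw)

   The criteria are conjunctive: a window failing any one scores zero. For
   PKCβ this formalizes the selection of the C2Cat peptide
   KDRRLSVEIWDWDLT (residues 236–250), which contains the ψRACK motif
   SVEIWD.
4. **Quantify IHC cohorts**: positive-pixel-count bands (strong [0,100),
   positive [100,175), weak [175,220], negative (220,255]), per-sample
   positivity score 256 − mean intensity, and an unpaired two-sided t-test
   between cohorts (e.g. ER-positive vs triple-negative breast tumors).

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

Everything below runs offline on the package's own synthetic fixtures:

```bash
epistate run --stages simulate,build-model,scan,ihc --out demo --seed 0
```

`simulate` writes a toy P1 crystal in which the partner chain touches the
regulatory chain only through a lattice translation, a toy family alignment
with a conserved window planted over the interface, a simulated cohort table
(105 ER+ vs 29 triple-negative samples), and a ready-made `pipeline.cfg`.

`build-model` recovers the planted symmetry mate — `contacts.tsv`:

```text
res_a    res_b    distance_A  salt_bridge
A:LYS10  B:GLU10  3.000       True
```

i.e. the Lys–Glu pair planted across the cell boundary is found at 3.0 Å and
classified as a salt bridge; `provenance.json` records the generating
operator (`x,y,z` plus lattice shift `(-1,0,0)`) and the buried area.

`scan-epitopes` ranks 5-residue windows (window length set by the generated
config) — top of `candidates.tsv`:

```text
rank  start  end  sequence  burial_closed  exposure_open  conservation  divergence  composite
1     8      12   AAKAA     0.0561         0.3057         1.0000        0.6000      0.3185
2     7      11   AAAKA     0.0561         0.3057         0.9667        0.6000      0.3158
```

Rank 1 is exactly the planted window (residues 8–12): it covers the buried
interface residue and is fully conserved in the target family while
divergent in the off-target family.

`ihc-quant` compares the simulated cohorts — `report_ihc.json`:

```text
"means": [81.7593, 108.6408],   # ER+ vs triple-negative positivity scores
"n": [105, 29],
"t": -6.7264,
"p_two_sided": 4.79178e-10
```

The triple-negative cohort stains higher and the unpaired t-test rejects far
below the 1e-4 level, mirroring the tissue-microarray comparison the
quantification was designed for.

For a real use case, point `pipeline.cfg` at a deposited structure (e.g.
PKCβII, PDB 3PFQ, C2 domain 152–292), a cPKC/nPKC alignment with
`family.*` labels, and your slide manifest.

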