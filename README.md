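# cspfret

Quantitative analysis of a protein–protein interaction that remodels a
helical nucleoprotein filament, combining four measurement modalities in
one tested pipeline:

1. **NMR chemical-shift-perturbation (CSP) mapping** — per-residue weighted
   amide shift changes from HSQC titration peak lists, with statistical
   significance thresholds;
2. **binding-isotherm K_D fitting** — per-residue single-site dissociation
   constants from CSP-vs-concentration series;
3. **docking-restraint generation** — ambiguous interaction restraints
   (AIRs) from significant, solvent-accessible residues, plus docking
   cluster z-scores;
4. **single-molecule FRET burst analysis** — alternating-laser-excitation
   (ALEX) photon streams to stoichiometry-filtered burst E\* histograms and
   single-Gaussian fits, with a helical-filament forward model to interpret
   E\* shifts as stretch/untwist conformational changes.

The motivating system is the bacterial replication-initiation machinery:
DnaD (via its DDBH2 domain) binds domain I of the initiator DnaA and
remodels DnaA–DNA filaments. Because no raw spectra or photon streams are
deposited for such studies, a first-class synthetic-data module generates
every input with known ground truth, so the entire pipeline is testable
end to end.

## The quantities computed

**CSP** per residue between apo and bound states:

    CSP = sqrt( 1/2 [ Δδ_H² + (0.14·Δδ_N)² ] )

Residues with CSP above μ+σ or μ+2σ of the profile are significant.
(The weighting convention with 0.14 inside the square is the default; the
literal reading `0.14·Δδ_N²` is available via a flag.)

**K_D** from the depletion-corrected single-site isotherm, with total
labelled protein P and ligand L = ratio × P:

    CSP(L) = CSP_max · [ (P+L+K_D) − sqrt((P+L+K_D)² − 4PL) ] / (2P)

fitted per residue by least squares and averaged over well-resolved
reporter residues. Standard errors account for the error correlation
introduced by the shared apo reference spectrum.

**Burst quantities** from ALEX photon streams (DD: green-excitation
donor-channel counts; DA: green-excitation acceptor-channel; AA:
red-excitation acceptor-channel):

    E* = DA / (DD + DA)        S = (DD + DA) / (DD + DA + AA)

Bursts are located by an all-photon sliding-window search, filtered to
dual-labelled species by S ∈ [0.3, 0.8], and the E\* population is fitted
with an unbinned single Gaussian.

**Filament model**: subunit k of an ideal helix is rotated by k·twist and
translated by k·rise; labels are drawn per subunit at donor:acceptor:
unlabelled = 1:1:2, and the nearest donor–acceptor distance r maps to
E = 1/(1+(r/R₀)⁶).

## Worked example

Simulate a forward titration (K_D = 768 μM, 100 μM labelled protein,
17 points from 0:1 to 8:1), map the CSPs and fit the dissociation
constant:

```
cspfret simulate titration --preset titration_forward --seed 11 --out-dir run/titr
cspfret csp --manifest run/titr/manifest.yaml --out-prefix run/profile
cspfret fit-kd --manifest run/titr/manifest.yaml --residues 20,50,52,55,60 \
        --out run/kd.json
```

The CSP stage logs

    CSP profile: mu=0.0159 sigma=0.0302, 9 significant residues

i.e. exactly the nine planted interface residues exceed μ+σ, and the fit
stage reports an averaged K_D ≈ 785 μM over the five reporter residues
(truth: 768 μM; individual seeds scatter by a few percent). The smFRET
chain works the same way:

```
cspfret simulate photons --preset filament_alone --seed 3 --out run/photons.tsv
cspfret fret --photons run/photons.tsv --out-prefix run/fret
```

which prints `fitted E* = 0.691 +/- 0.081 over 2527 bursts` for the
unperturbed-filament regime (ground truth E\* = 0.70); the
`filament_plus_dnad` preset recovers E\* ≈ 0.50 and `filament_plus_ddbh2`
E\* ≈ 0.59, reproducing the remodelling shift of ≈ 0.2 and its
intermediate DDBH2 value.

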