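# pzbd

Analysis toolkit for the **putative zinc-binding domain (pZBD)** of
glutamyl-tRNA synthetase (GluRS) and its relatives (Glu-Q-RS, archaeal
and eukaryal GluRS).

## The scientific problem

Bacterial GluRS carries, inside its N-terminal catalytic domain, a small
domain bracketed by two β-strands (E3 and E4) that in *E. coli* binds a
Zn²⁺ ion through a gapped cysteine/tyrosine motif such as
`CxCx₂₀₋₂₁Yx₃C` (a "ZB-motif": four anchored residues whose side chains
can coordinate zinc, separated by fixed or bounded numbers of arbitrary
residues). Many bacterial GluRSs lack this motif; a few lack the domain
altogether. Three questions follow, and this package implements the
computational side of each:

1. **Which sequences have a ZB-motif, and how long are their pZBDs?**
   A gapped-motif scanner (exhaustive, reporting every realisation of
   every pattern) plus an anchored-alignment classifier that measures the
   pZBD as the ungapped stretch strictly between the E3/E4 anchor columns
   and files each sequence into five groups: I (canonical motif),
   II (modified motif), III (motif-free, ≥ 37 residues), IV (motif-free,
   31–36), V (pZBD-deleted, ≤ 17).
2. **How do motif-free pZBDs stay folded without zinc?** Geometric
   detectors over 3D coordinates: Zn²⁺ coordination spheres (e.g.
   "S3N1" = three sulfur + one nitrogen ligands), side-chain-mediated
   long-range hydrogen bonds (|i−j| ≥ 5), the conserved Tyr OH →
   backbone N(i+4) bond, arginine–aromatic cation–π contacts, and
   least-squares rigid superposition with RMSD.
3. **Why is the domain deletable in some bacteria?** Per-genome logic
   linking pZBD deletion to redundancy of the indirect glutaminylation
   pathway (GlnRS/GluRS2 presence, gatCAB presence, the tRNA^Gln U1-A72
   identity pair), with a two-sided exact 2×2 contingency test computed
   by full hypergeometric enumeration.

A kinetics module fits the wet-lab side — tryptophan-fluorescence
titrations with the exact (depletion-aware) 1:1 binding model

    f_bound(L) = ((E + L + K_d) − √((E + L + K_d)² − 4·E·L)) / (2E),

Michaelis–Menten glutamylation kinetics v = k_cat·E·[S]/(K_m + [S]), and
PAR/MMTS zinc-release calibrations — and derives catalytic efficiency
k_cat/K_m, fold changes, and binding free-energy differences
ΔΔG = RT·ln(K_d,variant/K_d,ref) (R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹,
T = 298.15 K).

A synthetic-data module generates every input class with known ground
truth (planted motifs, planted geometry, genome tables with a tunable
association, noisy titration/kinetics series), so the whole pipeline is
testable without any downloads.

## Worked example

```python
from pzbd import motifs, classify, simulate

# scan a sequence carrying the canonical bacterial motif
seq = "AA" + "CAC" + "A" * 20 + "Y" + "AAA" + "C" + "AA"
hits = motifs.scan_sequence(seq, motifs.catalog_for("bacteria-GluRS"))
print(hits[0].pattern_name, hits[0].anchored_positions, hits[0].matched_gaps)
# bact-I (2, 4, 25, 29) (1, 20, 3)

# generate a mixed cohort and classify it back
spec = simulate.CohortSpec(n_per_group={"I": 5, "III": 4, "V": 2}, seed=7)
records, truth, aligned, anchors = simulate.gen_sequence_cohort(spec)
anns = classify.annotate(aligned, anchors)
print({g: sum(a.group == g for a in anns) for g in ("I", "III", "V")})
# {'I': 5, 'III': 4, 'V': 2}
```

The first line reports one hit of the canonical pattern `bact-I` with its
four anchored residues at 0-based positions 2, 4, 25, 29 and realised
gaps (1, 20, 3). The cohort round trip recovers the planted composition
exactly.

From the shell, the same stages are available as `pzbd scan`,
`pzbd classify`, `pzbd structure`, `pzbd context`, `pzbd kin ...`,
`pzbd simulate ...` and `pzbd run --config run.yaml`. Running

```bash
pzbd paper-numbers
```

prints a table of every published summary quantity recomputed from the
packaged raw measurements (catalytic efficiencies, fold changes, ΔΔG
values, survey arithmetic, zinc stoichiometry) next to its printed value,
e.g. the wild-type efficiency row computes 81039.76 M⁻¹s⁻¹ against the
printed 8.1×10⁴.

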