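# refractive-outcomes

Standardized reporting of refractive-surgery outcomes. The package turns
per-eye refraction and visual-acuity records — one 20-column spreadsheet
per group — into the set of standard graphs that refractive-surgery
journals require with outcome submissions (cumulative visual acuity,
efficacy, safety, SEQ/DEQ accuracy, astigmatism vector analysis,
stability), with automatic, design-appropriate statistics for one- and
two-group studies. It is aimed at corneal and intraocular refractive
surgeons, researchers and trainees who need publication-ready outcome
figures and valid group comparisons without manual spreadsheet work.

## The quantities at the core

For a refraction with sphere *S*, cylinder *C* (negative-cylinder
notation) and axis θ at vertex distance *d*:

- **Spherical equivalent** SEQ = *S* + *C*/2; **defocus equivalent**
  DEQ = |SEQ| + |*C*|/2.
- **Vertex propagation** per principal meridian *F* → *F*/(1 − d·*F*),
  so −10.00 D at 12 mm is −8.93 D at the cornea.
- **Visual acuity**: 20/XX Snellen tokens with letter suffixes
  ("20−1", "25+2") map to logMAR = log₁₀(XX/20) − letters·0.02 and
  decimal acuity 10^(−logMAR). The **efficacy index** is mean decimal
  postop UDVA over mean decimal baseline CDVA; the **safety index** uses
  postop CDVA (baseline = preop CDVA, or postop CDVA for cataract
  surgery).
- **Astigmatism vectors** (doubled-angle / Alpins framework): a cylinder
  *C* @ θ becomes (*C* cos 2θ, *C* sin 2θ); the target-induced
  astigmatism TIA = target − preop and surgically-induced astigmatism
  SIA = postop − preop are ordinary vector differences in that space.
  The **correction index** CI = |SIA|/|TIA| and the **angle of error**
  is half the signed doubled-angle between SIA and TIA.
- **Statistics**: each panel variable is screened for normality
  (Lilliefors-corrected Kolmogorov–Smirnov); two groups are compared
  with an unpaired/paired t-test when both samples pass, otherwise
  Mann–Whitney U / Wilcoxon signed-rank; Cohen's *d* is always reported
  (|d| < 0.20: not clinically relevant).

## Worked example

```python
from refractive_outcomes import Refraction, propagate_vertex, vector_outcome

preop  = propagate_vertex(Refraction(-1.00, -2.00, 10, vertex=12), 0)
target = Refraction(0, 0, 180, vertex=0)
postop = propagate_vertex(Refraction(-0.25, -0.50, 5, vertex=12), 0)
out = vector_outcome(preop, target, postop)
print(f"TIA {out.tia.magnitude:.2f} D, CI {out.correction_index:.2f}, "
      f"AoE {out.angle_of_error:+.1f} deg")
```

prints

```
TIA 1.91 D, CI 0.75, AoE +1.7 deg
```

— the intended correction was 1.91 D of (corneal-plane) cylinder; only
75 % of that magnitude was achieved (undercorrection), with the achieved
axis 1.7° counterclockwise of the intended one.

A full study runs from the shell:

```bash
refractive-outcomes --procedure CAT --design unpaired \
    --group-a groupA.csv --group-b groupB.csv --out results/
```

which writes ten panel TIFFs at 400 dpi, a one-page composite at
1200 dpi, a `stats_summary.csv` of per-panel tests and a run log. The
`examples/` directory holds one short script per capability (optical
algebra, acuity indices, vector analysis, single-group simulation, full
two-group workflow); each prints the numbers it computes and what they
mean. Synthetic study generators (`refractive_outcomes.simulate`)
produce realistic cohorts in the exact input format, including three
presets: a paired contralateral-eye laser comparison, a single-group
toric phakic IOL cohort, and a two-group cataract comparison.

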