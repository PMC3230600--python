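# nemaquant

Tissue-level quantification of histochemically stained *C. elegans*
fresh-frozen sections.

Histochemistry on worm cross-sections makes metabolic state visible tissue
by tissue — enzymatic activity stains for the respiratory-chain complexes
(NADH dehydrogenase, succinate dehydrogenase, cytochrome c oxidase) darken
in proportion to local enzyme activity, and Oil-Red-O marks neutral lipid
stores red against a blue hematoxylin counterstain.  `nemaquant` is the
analysis half of that workflow: it takes micrographs plus ImageJ-style ROI
annotations and turns them into calibrated, statistically summarized
numbers.  It is aimed at worm labs doing sectioned histochemistry and at
anyone who needs a scriptable, reproducible replacement for interactive
ImageJ measurement.

## What it computes

**ROI densitometry** (enzymatic stains).  For each tissue ROI paired with
its geometrically closest local background ROI,

    OD = log10(I_bk / I_m)

where `I_bk` and `I_m` are mean 8-bit intensities of background and sample.
Mutant activities are normalized to a wild-type reference, comparing only
sections stained on the same glass slide, and reported with 95% t
confidence intervals and pooled-variance Student's t-tests.

**Oil-Red-O lipid quantification.**  The two-step segmentation: (1) an
automatic IsoData (iterative intermeans) grayscale threshold separates the
section from the bright background; (2) each section pixel is classified by
its dominant color channel — `R > B and R > G` → red (lipid),
`B > R and B > G` → blue (counterstain), anything else unclassified.  The
lipid statistic is the positivity ratio

    PX_red / (PX_red + PX_blue)

per section or per tissue ROI, plus the distribution of red pixels across
tissues.

**Staining kinetics.**  OD-versus-time traces extracted from reaction image
stacks are fitted with a four-parameter logistic
`od(t) = baseline + A / (1 + exp(-k (t - t_mid)))`; the exponential phase —
within which reactions must be stopped for valid quantification — is
bounded by the inflection-tangent construction `t_mid ± 2/k`.

**Synthetic validation data.**  Seeded generators render stained-section
images, OD panels and kinetics traces with exact ground truth, so the whole
pipeline is testable without any micrograph.

## Worked example

```python
import nemaquant as nq

# render a lipid-rich mutant section with known per-tissue red fractions
img, rois, truth = nq.generate_section("daf2", seed=5)

# full two-step segmentation + per-tissue quantification
profile = nq.tissue_lipid_profile(img, rois)
for tissue in ("intestine", "germline_distal", "germline_proximal"):
    r = profile.per_tissue[tissue]
    print(f"{tissue:20s} ratio={r.ratio:.3f} "
          f"(truth {truth.lipid_fraction[tissue]:.3f})")

# staining kinetics: where is the exponential phase?
trace, _ = nq.generate_kinetics("nadh_20C", seed=5)
fit = nq.fit_logistic(trace)
onset, end = nq.exponential_phase(trace, fit)
print(f"NADH exponential phase: {onset:.2f} - {end:.2f} min")
```

prints

```
intestine            ratio=0.600 (truth 0.600)
germline_distal      ratio=0.160 (truth 0.160)
germline_proximal    ratio=0.400 (truth 0.400)
NADH exponential phase: 5.00 - 9.03 min
```

The measured Oil-Red-O positivity ratios recover the generator's built-in
lipid fractions (the `daf2` preset doubles every wild-type fraction), and
the kinetics detector finds the onset of the exponential staining phase at
5 minutes — stop an NADH reaction inside that window.

The same operations are available from the shell:

```sh
nemaquant simulate section --preset n2 --seed 1 --out demo/
nemaquant oilred --image demo/n2_seed1.png --rois demo/n2_seed1_rois.zip \
    --out demo/n2.csv --segmentation-out demo/n2_classes.png
nemaquant kinetics --trace trace.csv --out fit.csv
nemaquant od-quant --config batch.yaml --out od.csv
```

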