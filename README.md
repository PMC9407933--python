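# iczone

Modeling the **Individual Convenient Zone (ICZ)** — the space a person's
upper limb can reach, annotated at every point with the maximum upward
force the person can exert there — and using it to fit product layouts
(kitchen furniture, workstations) to a specific person.

Averaged anthropometric and strength atlases describe percentile humans,
not *this* senior or *this* wheelchair user. Full laboratory
characterization of one person's reach/strength space takes hundreds of
supervised force measurements, which is impractical at a point of sale.
`iczone` implements the alternative workflow:

1. **Repository** — fully measured subjects are stored as point clouds of
   force measurements in a body-centered cylindrical frame
   (angle α about the body axis, height *z*, radius *r*), interpolated
   into a lattice strength field with monotone non-increasing force
   along every ray (force drops as the hand moves away from the body).
2. **Quick matching** — a prospective user is characterized by five
   quickly measurable values: forces *F₁*–*F₄* (N) at defined points of
   the reach space and the anterior reach *D₁* (cm). Each value *Aᵢ* is
   min–max normalized against the repository bounds,

   &nbsp;&nbsp;&nbsp;&nbsp;*aᵢ* = (*Aᵢ* − *Aᵢ*ₘᵢₙ) / (*Aᵢ*ₘₐₓ − *Aᵢ*ₘᵢₙ),

   and the dissimilarity between a repository entry *b* and the user *u*
   is the mean absolute difference of normalized features

   &nbsp;&nbsp;&nbsp;&nbsp;sim(*x*) = (1/5) Σᵢ |*aᵢᵦ* − *aᵢᵤ*|,

   with 0 = entirely similar and 1 = entirely different. The
   closest repository entry's full zone stands in for the user's.
3. **Ergonomic assessment** — constant-strength layers (iso-force
   surfaces) of the matched zone, proportionally rescaled from
   laboratory limit forces *F* to allowable working forces
   *F_d* = *k·F*, are exported as CAD meshes, and task layouts are
   checked point by point for reachability and force adequacy.

## Worked example

The package bundles a 12-subject repository worksheet together with one
prospective user (a 72-year-old, 175 cm tall, 84 kg; measured
*F₁ᵤ* = 71 N, *F₂ᵤ* = 57 N, *F₃ᵤ* = 146 N, *F₄ᵤ* = 110 N,
*D₁ᵤ* = 68 cm, normalized vector 0.564, 0.485, 0.557, 0.739, 0.824):

```bash
python -c "import iczone as iz; iz.save_repository(iz.example_worksheet().table, 'repo.csv')"
icz match --repo repo.csv --normalized 0.564,0.485,0.557,0.739,0.824
```

prints

```
best match: entry 7 (sim(x) = 0.085)
  entry 7: per-feature [0.218 0.177 0.023 0.008 0.000]  total 0.085
  entry 3: per-feature [0.090 0.073 0.138 0.294 0.118]  total 0.143
  entry 1: per-feature [0.115 0.103 0.120 0.277 0.176]  total 0.158
  ...
  entry 6: per-feature [0.564 0.485 0.557 0.739 0.117]  total 0.492
```

Entry 7 (F₁ = 88 N, F₂ = 69 N, F₃ = 150 N, F₄ = 117 N, D₁ = 68 cm) is
the best match at sim(*x*) = 0.085: its full laboratory zone model is
the one a designer would load for this user. Note the per-feature
values show why a globally best match can lose individual features —
entry 5 is closer on *F₁* alone (0.064 vs 0.218) but much worse overall
(0.347). The same repository summary is available via `icz repo
repo.csv`, which prints the per-feature bounds (F₁: 27–105 N, …,
D₁: 54–71 cm) that drive the normalization.

Downstream, with a full model JSON (`icz synth` generates synthetic
ones for experimentation):

```bash
icz layers --model subject.json --levels 35,60 --fd-scale 0.35 --export-dir out/
icz assess --model subject.json --layout kitchen.csv --fd-scale 0.35 --report report.json
```

export the *F_d* = 35 N and 60 N constant-strength surfaces (ASCII
OBJ/STL, cm, z-up) and verdict every layout point as `OK`,
`FORCE_INADEQUATE` or `OUT_OF_REACH` with its available force and
margin.

## Layout

* `src/iczone/core_model.py` — domain types, field interpolation,
  constant-strength layers, proportional rescaling, feature extraction
* `src/iczone/repository.py` — feature tables, bounds, CSV/JSON I/O
* `src/iczone/similarity.py` — normalization, sim(x), best-match retrieval
* `src/iczone/ergonomics.py` — layout assessment and mesh export
* `src/iczone/synthetic.py` — synthetic point-cloud generator and the
  bundled example worksheet
* `src/iczone/cli.py` — the `icz` command line
* `docs/methods.md` — modeling assumptions, parameters and numerical
  choices
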