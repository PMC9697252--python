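# mpfusion

Multi-perspective hierarchical deep-fusion learning for classifying 3D
volumes of interest (VOIs) as **nodule** vs **non-nodule**, the core
false-positive-reduction step of a lung-CT computer-aided detection (CAD)
pipeline — together with a synthetic phantom generator so the whole pipeline
can be exercised, trained, and evaluated without any imaging archive.

## Who this is for

Researchers building or studying decision-level fusion of multi-view CNNs:
the package provides the full stack — annotated 3D phantom generation,
multi-reader consensus, physical-unit VOI extraction, feature-image filters
(including an edge-and-curvature-preserving trilateral filter), a compact
slice CNN, the stacked fusion levels, and level-wise evaluation.

## The model

A VOI is a 30×30×30 mm³ cube around a lesion's consensus center, resampled
to 56³ voxels and sliced along three orthogonal perspectives (transverse XY,
coronal XZ, sagittal YZ); six planes per perspective are selected at equal
intervals across the object's span. Classification is hierarchical and
trained **modularly**, one level at a time on the frozen outputs of the
level below:

1. **Slice modules MS₁..MS₃** — one small CNN per perspective
   (four 3×3-conv + ReLU + 2×2-max-pool blocks with 8/16/32/64 filters,
   a 32-unit fully connected layer, softmax head; spatial trace
   56→28→14→7→3) scores every slice,
   trained with cross-entropy `L = −Σⱼ tⱼ log pⱼ`.
2. **Perspective modules MP₁..MP₃** — a one-hidden-layer feedforward net
   maps each perspective's 6-vector of slice scores to one score per
   perspective.
3. **Volume module MV** — the same kind of net maps the (MP₁, MP₂, MP₃)
   3-vector to the final decision.

Variants: the same hierarchy run on **feature images** instead of raw slices
(LoG, Gabor, bilateral, or trilateral filtered slices — single-feature
fusion), and a **multi-feature** top level that stacks the volume scores of
several such fitted models.

The trilateral filter extends the bilateral windowed mean

    I_B(c) = (1/W) Σ_r S(r;c,σ_S) · R(I(r);I(c),σ_R) · I(r)

with a third Gaussian kernel `L(Δ∇²I(r;c); σ_L)` on the neighbour-minus-
centre difference of discrete Laplacian responses, penalising
gradient-variation mismatch around high-frequency structure.

## Worked example

```python
import mpfusion as mp

# phantom scans with 4 jittered simulated readers per object
scans, annotations = mp.generate_dataset(n_scans=151, objects_per_scan=4,
                                         separability="easy", seed=42)
objects = mp.build_consensus(annotations)          # merge + conflict removal
scan_map = {s.scan_id: s for s in scans}
vois = [mp.extract_voi(scan_map[o.source_scan], o) for o in objects]
train, test = mp.split_dataset(vois, train_frac=0.7, seed=0)

model = mp.HierarchicalFusion(train)               # raw-slice fusion
results = model.fit(seed=0)                        # MS -> MP -> MV, modular
report = results.evaluate(test)
print(report.table)
```

which printed (seed 0, this machine):

```
         level perspective       acc       auc        f1      sens      spec
0        slice          V1  0.909341  0.975221  0.906339  0.877289  0.941392
1        slice          V2  0.912088  0.970770  0.911765  0.908425  0.915751
2        slice          V3  0.896520  0.960264  0.891659  0.851648  0.941392
3  perspective          V1  0.989011  0.999879  0.988889  0.978022  1.000000
4  perspective          V2  0.983516  0.996981  0.983425  0.978022  0.989011
5  perspective          V3  0.978022  0.998430  0.978022  0.978022  0.978022
6       volume         all  0.989011  1.000000  0.988889  0.978022  1.000000
```

Reading the table: each row is one evaluation unit at one level — slices as
units at the slice level, whole VOIs above.  Accuracy climbs from ~0.90–0.92
(single slices) through ~0.98 (per-perspective fusion of six slice scores)
to 0.989 at the volume level: each fusion level corrects errors that the
level below makes on individual views, the central property of the
hierarchical scheme.  `report.fp_per_scan` gives false-positive object calls
per distinct scan (0.0 here).

A single-feature variant only needs a filter:

```python
sfm = mp.HierarchicalFusion(train, feature_spec=mp.FilterSpec(family="trilateral"))
```

A thin CLI covers the same steps (`mpfusion simulate / extract / filter /
train / evaluate`).

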