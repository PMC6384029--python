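# tripletomo

Quantitative analysis of procentriole microtubule-triplet architecture from
cryo-electron tomography, exercised end-to-end on a synthetic 9-fold
triplet-array generator.

The procentriole — the precursor of a daughter centriole — is a barrel of
nine microtubule (MT) triplet "blades" built around a cartwheel hub. Each
blade carries a complete 13-protofilament (PF) A-tubule and partial 10-PF B-
and C-tubules, decorated by microtubule inner proteins (MIPs), the pinhead
hook that anchors the blade to a cartwheel spoke (8 nm axial repeat, on top
of the 4 nm tubulin monomer repeat), and the A-C linker that bridges
neighbouring blades. Subtomogram averaging of such assemblies must contend
with the ±60° missing wedge, with blades that twist progressively along the
long axis (an iris-diaphragm motion), and with partially assembled B- and
C-tubules at the growing ends.

`tripletomo` provides, as a tested reusable library:

* **`geometry`** — a parametric procentriole model: PF ring specifications,
  decorations, a linear twist profile θ(z) = θ₀ + r·z with handedness
  conventions, and closed-form geometry such as the interior angle
  (n − 2)·180°/n a nonagon imposes between neighbouring blades.
* **`simulate`** — rendering of the model into density volumes (continuous
  PF wall tubes with 4 nm monomer bumps, decorations at their own repeat),
  the missing-wedge projection operator, and a subtomogram simulator with
  ground-truth poses, assembly intermediates (B1–B3-only B-tubules,
  C1–C3 + C8–C10 C-tubules) and per-filament tubule-length variation.
* **`align`** — wedge-constrained cross-correlation, grid + simplex rigid
  alignment, and gold-standard (even/odd) wedge-normalised averaging.
* **`ransac`** — the filament constraint: per-parameter RANSAC polynomial
  regression of pose parameters along each filament's arc length, flagging
  alignment outliers and correcting them by the regression prediction.
* **`classify`** — wedge-aware multi-reference (k-means style) focused
  classification to detect incomplete tubules and A-C linker conformers,
  plus positional mapping of intermediates into five classes (proximal end,
  distal end, nascent, short < 10 nm, mid).
* **`quantify`** — count-weighted twist angles T_i = Σⱼ θⱼN_ij / Σⱼ N_ij and
  swing range, gold-standard FSC with the 0.143 criterion, longitudinal
  periodicity estimation, difference-map MIP segmentation with molecular
  weight = 0.849 Da/Å³ × volume, and tubule-length statistics.
* **`pipeline` / CLI** — the staged pipeline (simulate → align → constrain →
  classify → average → quantify) with per-stage manifests and a subtomogram
  count ledger.

## Worked example

```python
import numpy as np
from tripletomo.geometry import interior_angle
from tripletomo.quantify import (ClassCountTable, weighted_twist,
                                 swing_range, mass_from_volume)

# the blade-to-blade angle a closed 9-fold array requires
print(interior_angle(9))            # 140.0

# weighted twist angle at three longitudinal points from class counts
counts = np.array([[12, 30, 25, 8],
                   [10, 28, 30, 9],
                   [ 6, 22, 35, 14]])
table = ClassCountTable([93, 90, 87, 83], counts, points_nm=[0, 18, 36])
print(np.round(weighted_twist(table), 2))   # [88.73 88.4  87.6 ]
print(swing_range(table))                   # 10.0

# molecular weight of a 53,004 Å³ segmented density
print(mass_from_volume(53004.0) / 1000.0)   # 45.000396  (kDa)
```

The weighted angles drift towards the smaller class angles with increasing
longitudinal position — the signature of the progressive left-handed twist —
and the swing range is the spread of the class angles themselves.

A full synthetic run (9 filaments, SNR 0.5, left-handed twist at
0.12°/nm):

```sh
tripletomo run --out run1 --seed 17
```

writes per-stage manifests plus `summary.json`; in a run with the default
configuration the recovered `twist_rate_deg_per_nm` was 0.123 with
`handedness: left` (true rate 0.12) and the gold-standard FSC of the final
average crossed 0.143 at 3.1 nm.

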