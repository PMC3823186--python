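# Input templates

## `cohort_template.csv`

One row per participant. Empty cells are missing values (allowed for the
amputation-specific fields only in the `control` group); never encode
missing data as 0.

| column | meaning | codes |
|---|---|---|
| `participant_id` | opaque label | — |
| `group` | cohort group | `congenital`, `acquired`, `control` |
| `amputation_level` | where the residual arm ends | 1 = through shoulder, 2 = above elbow, 3 = through elbow, 4 = below elbow, 5 = through wrist |
| `side` | side of limb absence | `L` / `R` |
| `deprivation_age` | age at limb loss (years); 0 for congenital absence | ≥ 0 |
| `cosmetic_prosthesis_usage` | usage frequency | 0 = never … 5 = more than 8 h a day |
| `functional_prosthesis_usage` | usage frequency | 0 = never … 5 = more than 8 h a day |
| `mal_score` | modified Motor Activity Log score | fraction in [0, 1] |
| `pain_intensity` | phantom pain intensity | 0 = no pain … 10 = worst imaginable |
| `pain_frequency` | phantom pain frequency | 1 = all the time, 2 = daily, 3 = weekly, 4 = several times per month, 5 = once or less per month |
| `laterality_index` | movement laterality index | fraction in [−1, 1] |
| `beta_intact_hand` | ROI activation estimate during intact-hand movement | arbitrary units (externally supplied) |
| `beta_residual_arm` | ROI activation estimate during residual-arm movement | arbitrary units (externally supplied) |

## `mal_questionnaire_template.csv`

One row per participant: `participant_id` plus the 27 item columns (short
codes defined in `limbuse.metrics.MAL_ITEMS`), each rated
0 = never, 1 = sometimes, 2 = very often. All items must be answered.

## Raw recordings

One CSV per limb named `<participant>_<limb>[_<day>].csv` with limb
`intact` or `residual`, header `time_s,ax_ms2,ay_ms2,az_ms2`, accelerations
in m/s² (gravity included), sampled uniformly (default 100 Hz).
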