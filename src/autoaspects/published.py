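"""Published clinical benchmark values for automated ASPECTS reading.

These are the printed summary metrics of a reader study on a 90-patient
acute-stroke NCCT test cohort (180 hemisphere-region instances per
ASPECTS region): per-region performance of the automated reader, the
pooled line over all regions, and per-physician performance (an ER
physician, a neurologist, a radiologist and a neuroradiologist) with and
without algorithmic assistance, at region level and after dichotomizing
at ASPECTS >= 6.

They are *inputs* to the verification bridge in
:mod:`autoaspects.stats`: the (sensitivity, specificity, accuracy,
precision) quadruples printed to three significant figures uniquely
determine the underlying integer confusion matrices at n = 180, from
which every derived F1 and kappa cell and the pooled line can be
recomputed and checked.

Percentages are stored as printed (40.9 means 40.9%); F1, kappa, ICC and
AUC as unitless values.
"""

from __future__ import annotations

__all__ = ["N_TEST_PATIENTS", "N_REGION_INSTANCES", "REGION_ROWS", "POOLED_ROW",
           "PHYSICIAN_REGION_ROWS", "PHYSICIAN_DICH_ROWS", "DLAD_DICH_ROW",
           "MEAN_PHYSICIAN_REGION", "MEAN_PHYSICIAN_DICH", "READERS"]

N_TEST_PATIENTS = 90
#: hemisphere-region instances per ASPECTS region (2 hemispheres x 90 patients)
N_REGION_INSTANCES = 180

READERS = ("er_physician", "neurologist", "radiologist", "neuroradiologist")

#: automated reader, per region: sens%, spec%, acc%, prec%, F1, kappa, AUC
REGION_ROWS = {
    "caudate":          (40.9, 93.7, 87.2, 47.4, 0.439, 0.367, 0.770),
    "putamen":          (86.5, 55.9, 62.2, 33.7, 0.485, 0.268, 0.822),
    "internal_capsule": (64.3, 68.7, 68.3, 14.8, 0.240, 0.130, 0.691),
    "insula":           (87.1, 67.8, 71.1, 36.0, 0.509, 0.351, 0.878),
    "M1":               (63.6, 95.3, 93.3, 46.7, 0.538, 0.503, 0.854),
    "M2":               (76.2, 88.7, 87.2, 47.1, 0.582, 0.511, 0.868),
    "M3":               (33.3, 85.2, 80.0, 20.0, 0.250, 0.143, 0.652),
    "M4":               (72.7, 88.8, 87.8, 29.6, 0.421, 0.366, 0.832),
    "M5":               (58.3, 80.1, 77.2, 31.1, 0.406, 0.281, 0.757),
    "M6":               (38.9, 87.7, 82.8, 25.9, 0.311, 0.217, 0.638),
}

#: automated reader pooled over all regions: sens%, spec%, acc%, F1, kappa, AUC
POOLED_ROW = (65.2, 81.6, 79.7, 0.43, 0.32, 0.73)

#: per-physician region-level rows: {reader: {"alone"|"with_dlad":
#:   (sens%, spec%, acc%, F1, kappa, AUC)}}
PHYSICIAN_REGION_ROWS = {
    "er_physician":    {"alone": (15.9, 97.0, 87.7, 0.23, 0.18, 0.56),
                        "with_dlad": (44.9, 93.8, 88.2, 0.47, 0.40, 0.69)},
    "neurologist":     {"alone": (30.4, 95.4, 87.9, 0.37, 0.30, 0.63),
                        "with_dlad": (66.7, 87.8, 85.4, 0.51, 0.43, 0.77)},
    "radiologist":     {"alone": (37.2, 93.7, 87.2, 0.40, 0.33, 0.65),
                        "with_dlad": (52.2, 92.8, 88.1, 0.50, 0.44, 0.72)},
    "neuroradiologist": {"alone": (51.7, 94.7, 89.7, 0.54, 0.48, 0.73),
                         "with_dlad": (51.2, 94.1, 89.2, 0.52, 0.46, 0.73)},
}

#: automated reader, dichotomized >=6 vs <6: sens%, spec%, acc%, F1, ICC, AUC
DLAD_DICH_ROW = (72.2, 90.7, 88.9, 0.57, 0.68, 0.82)

#: per-physician dichotomized rows: (sens%, spec%, acc%, F1, ICC, AUC)
PHYSICIAN_DICH_ROWS = {
    "er_physician":    {"alone": (5.6, 100.0, 90.6, 0.11, 0.19, 0.53),
                        "with_dlad": (27.8, 96.3, 89.4, 0.34, 0.45, 0.62)},
    "neurologist":     {"alone": (27.8, 98.1, 91.1, 0.38, 0.52, 0.63),
                        "with_dlad": (72.2, 90.1, 88.3, 0.55, 0.67, 0.81)},
    "radiologist":     {"alone": (22.2, 99.4, 91.7, 0.35, 0.50, 0.61),
                        "with_dlad": (50.0, 98.1, 93.3, 0.60, 0.73, 0.74)},
    "neuroradiologist": {"alone": (50.0, 95.7, 91.1, 0.53, 0.65, 0.73),
                         "with_dlad": (61.1, 95.1, 91.7, 0.59, 0.71, 0.78)},
}

#: reported mean physician metrics, region level:
#: {"alone"|"with_dlad": (sens%, spec%, acc%, F1, kappa)}
MEAN_PHYSICIAN_REGION = {"alone": (33.8, 95.2, 88.1, 0.38, 0.32),
                         "with_dlad": (53.7, 92.1, 87.7, 0.50, 0.43)}

#: reported mean physician metrics, dichotomized:
#: {"alone"|"with_dlad": (sens%, spec%, acc%, F1, ICC)}
MEAN_PHYSICIAN_DICH = {"alone": (26.4, 98.3, 91.1, 0.34, 0.46),
                       "with_dlad": (52.8, 94.9, 90.7, 0.52, 0.64)}
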