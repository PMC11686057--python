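"""Summary statistics of the clinical reference cohort.

These are the observed frequencies the synthetic cohort generator
emulates: a 33-lesion series (27 acquired with respiratory triggering,
six free-breathing), of which six were excluded for artifacts and 27
analyzed for the volume comparison.  Grades use a 1-5 ordinal scale
(1 = perfect, 5 = uninterpretable / no match).
"""

from __future__ import annotations

#: thermometry signal-to-noise quality grade -> lesion count (analyzed lesions)
QUALITY_GRADE_COUNTS = {1: 15, 2: 8, 3: 4}

#: movement-artifact grade -> lesion count
MOVEMENT_GRADE_COUNTS = {1: 18, 2: 8, 3: 1}

#: dose-shape vs ablation-zone shape match grade -> lesion count
SHAPE_GRADE_COUNTS = {1: 23, 2: 3, 3: 1}

#: lesions excluded for artifacts / total lesions with thermometry
EXCLUDED_LESIONS = 6
TOTAL_LESIONS = 33
ANALYZED_LESIONS = 27

#: 2x2 table of major artifacts by acquisition mode:
#: rows = (free breathing, respiratory triggered), cols = (artifact, no artifact)
TRIGGERING_ARTIFACT_TABLE = ((3, 3), (3, 24))

#: 2x2 table of major artifacts by liver lobe:
#: rows = (right lobe, left lobe), cols = (artifact, no artifact)
LOBE_ARTIFACT_TABLE = ((4, 20), (2, 7))

#: volume scale of the analyzed lesions (mm^3): median predicted lethal
#: volume and its interquartile range, and the day-1 ablation-zone median
PREDICTED_VOLUME_MEDIAN_MM3 = 16296.0
PREDICTED_VOLUME_IQR_MM3 = (13502.0, 21155.0)
DAY1_VOLUME_MEDIAN_MM3 = 16338.0

#: reported correlation between predicted and day-1 volumes
VOLUME_CORRELATION = 0.893
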