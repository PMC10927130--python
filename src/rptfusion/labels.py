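"""Canonical label sets for the analysis grid.

The regression grid is fixed at 29 total-brain-normalized regional volumes
by 15 keypress metrics (435 cells per group).  Both registries are plain
tuples so user code can supply its own label sets anywhere a function takes
``volumes=`` / ``metrics=``.
"""

from __future__ import annotations

#: The three diagnostic groups: healthy controls, major depressive disorder,
#: cocaine-dependence polysubstance use.
GROUPS: tuple[str, ...] = ("CTRL", "MDD", "CD")

#: 29 anatomist-segmented regional volumes, expressed as fractions of total
#: brain volume.  Right/left homologues are separate entries.
VOLUMES: tuple[str, ...] = (
    "Right Cerebral White Matter",
    "Left Cerebral White Matter",
    "Right Cerebral Cortex",
    "Left Cerebral Cortex",
    "Right Cerebellum White Matter",
    "Left Cerebellum White Matter",
    "Right Cerebellum Cortex",
    "Left Cerebellum Cortex",
    "Right Cerebellum (Exterior)",
    "Left Cerebellum (Exterior)",
    "Right Thalamus",
    "Left Thalamus",
    "Right Caudate",
    "Left Caudate",
    "Right Putamen",
    "Left Putamen",
    "Right Pallidum",
    "Left Pallidum",
    "Right Hippocampus",
    "Left Hippocampus",
    "Right Amygdala",
    "Left Amygdala",
    "Right Amygdala (Anterior)",
    "Left Amygdala (Anterior)",
    "Right Ventral Diencephalon",
    "Left Ventral Diencephalon",
    "Right Nucleus Accumbens",
    "Left Nucleus Accumbens",
    "Brain Stem",
)

#: The 15 keypress metrics: nine relative-preference-theory (RPT) graph
#: features plus the six base variables they are derived from.
METRICS: tuple[str, ...] = (
    "loss_resilience",
    "negative_offset",
    "negative_apex",
    "negative_turning_point",
    "negative_area",
    "polar_angle",
    "polar_dispersion",
    "radial_distance",
    "radial_dispersion",
    "mean_k_inc",
    "mean_k_dec",
    "mean_h_inc",
    "mean_h_dec",
    "mean_std_inc",
    "mean_std_dec",
)

#: The nine RPT graph features (subset of METRICS).
RPT_FEATURES: tuple[str, ...] = METRICS[:9]

#: The six base variables (subset of METRICS).
BASE_VARIABLES: tuple[str, ...] = METRICS[9:]

#: Demographic columns carried on the participant table.
DEMOGRAPHICS: tuple[str, ...] = ("gender", "age", "ethnicity", "education")

#: Valence codes used in the raw response table: "inc" = approach keypresses
#: (lengthen viewing time), "dec" = avoidance (shorten viewing time).
VALENCES: tuple[str, ...] = ("inc", "dec")
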