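"""AAL-90 parcellation labels and a-priori motor-circuit region sets.

The 90-node automated anatomical labeling (AAL) atlas is the standard
cortical + subcortical parcellation for resting-state connectivity work.
Nodes alternate left/right hemisphere in the canonical ordering
(Precentral_L, Precentral_R, ..., Temporal_Inf_R), cerebellum excluded.
"""

from __future__ import annotations

# 45 bilateral structures in canonical AAL order (L then R for each).
AAL90_STRUCTURES: tuple[str, ...] = (
    "Precentral",
    "Frontal_Sup",
    "Frontal_Sup_Orb",
    "Frontal_Mid",
    "Frontal_Mid_Orb",
    "Frontal_Inf_Oper",
    "Frontal_Inf_Tri",
    "Frontal_Inf_Orb",
    "Rolandic_Oper",
    "Supp_Motor_Area",
    "Olfactory",
    "Frontal_Sup_Medial",
    "Frontal_Med_Orb",
    "Rectus",
    "Insula",
    "Cingulum_Ant",
    "Cingulum_Mid",
    "Cingulum_Post",
    "Hippocampus",
    "ParaHippocampal",
    "Amygdala",
    "Calcarine",
    "Cuneus",
    "Lingual",
    "Occipital_Sup",
    "Occipital_Mid",
    "Occipital_Inf",
    "Fusiform",
    "Postcentral",
    "Parietal_Sup",
    "Parietal_Inf",
    "SupraMarginal",
    "Angular",
    "Precuneus",
    "Paracentral_Lobule",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Thalamus",
    "Heschl",
    "Temporal_Sup",
    "Temporal_Pole_Sup",
    "Temporal_Mid",
    "Temporal_Pole_Mid",
    "Temporal_Inf",
)

#: full 90-label list, "Structure_L" / "Structure_R" alternating
AAL90_LABELS: tuple[str, ...] = tuple(
    f"{name}_{hemi}" for name in AAL90_STRUCTURES for hemi in ("L", "R")
)

#: the eight a-priori motor structures of the cortico-striato-thalamo-cortical
#: loop used for delta-controllability / outcome correlations
MOTOR_STRUCTURES: tuple[str, ...] = (
    "Caudate",
    "Putamen",
    "Pallidum",
    "Thalamus",
    "Precentral",
    "Postcentral",
    "Supp_Motor_Area",
    "Paracentral_Lobule",
)

#: structures whose connectivity the synthetic generator perturbs in the
#: patient state (striato-pallido-thalamic nuclei plus sensorimotor cortex)
DISEASE_STRUCTURES: tuple[str, ...] = (
    "Caudate",
    "Putamen",
    "Pallidum",
    "Thalamus",
    "Precentral",
    "Postcentral",
)


def label_index(label: str, labels: tuple[str, ...] | list[str] = AAL90_LABELS) -> int:
    """Index of an atlas label within an ordered label list."""
    return list(labels).index(label)


def structure_indices(
    structures: tuple[str, ...] | list[str],
    labels: tuple[str, ...] | list[str] = AAL90_LABELS,
) -> list[int]:
    """Node indices (both hemispheres) for the given base structure names."""
    wanted = {f"{s}_{h}" for s in structures for h in ("L", "R")}
    return [i for i, lab in enumerate(labels) if lab in wanted]


def split_label(label: str) -> tuple[str, str]:
    """Split ``Structure_L`` into (``Structure``, ``L``)."""
    base, hemi = label.rsplit("_", 1)
    if hemi not in ("L", "R"):
        raise ValueError(f"label {label!r} has no hemisphere suffix")
    return base, hemi
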