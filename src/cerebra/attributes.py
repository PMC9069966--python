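"""The 66 experiential attribute labels used by CAR vectors.

Concept Attribute Representation (CAR) theory describes a concept as a
weighting over ~66 experiential attributes (visual, motor, auditory,
spatial, temporal, affective, social and cognitive), each tied to a brain
system. The default label list below is assembled from the attribute names
in common use with this feature set; a project with its own canonical label
list can pass it wherever an ``attributes`` argument is accepted — only the
count (66) is fixed.
"""

from __future__ import annotations

ATTRIBUTES: tuple[str, ...] = (
    # vision
    "Vision", "Bright", "Dark", "Color", "Pattern", "Large", "Small",
    "Motion", "Biomotion", "Fast", "Slow", "Shape", "Complexity",
    "Face", "Body",
    # somatosensory
    "Touch", "Temperature", "Texture", "Weight", "Pain",
    # audition
    "Audition", "Loud", "Low", "High", "Sound", "Music", "Speech",
    # gustation / olfaction
    "Taste", "Smell",
    # motor
    "Head", "UpperLimb", "LowerLimb", "Manipulation", "Practice",
    # spatial
    "Landmark", "Path", "Scene", "Near", "Toward", "Away",
    # quantity / time
    "Number", "Time", "Duration", "Long", "Short",
    # causal / event
    "Caused", "Consequential",
    # social / cognition
    "Social", "Human", "Communication", "Self", "Cognition",
    # evaluation
    "Benefit", "Harm", "Pleasant", "Unpleasant",
    # emotion
    "Happy", "Sad", "Angry", "Disgusted", "Fearful", "Surprised",
    # drive / attention
    "Drive", "Needs", "Attention", "Arousal",
)

N_ATTRIBUTES = len(ATTRIBUTES)
assert N_ATTRIBUTES == 66

# Attribute blocks used by the synthetic lexicon generator to give words
# animate / object / action category structure (e.g. animate concepts load
# on Face/Body/Biomotion/social-emotional attributes, objects on visual and
# somatosensory ones). Remaining attributes are shared across categories.
ANIMATE_BLOCK: tuple[str, ...] = (
    "Biomotion", "Face", "Body", "Human", "Social", "Communication",
    "Speech", "Self", "Cognition", "Happy", "Sad", "Angry", "Disgusted",
    "Fearful", "Surprised",
)
OBJECT_BLOCK: tuple[str, ...] = (
    "Vision", "Bright", "Dark", "Color", "Pattern", "Large", "Small",
    "Shape", "Complexity", "Touch", "Temperature", "Texture", "Weight",
    "Taste", "Smell", "Landmark", "Scene", "Near",
)
ACTION_BLOCK: tuple[str, ...] = (
    "Motion", "Fast", "Slow", "Path", "Toward", "Away", "Head",
    "UpperLimb", "LowerLimb", "Manipulation", "Practice", "Time",
    "Duration", "Long", "Short", "Caused", "Consequential",
)


def block_indices(block: tuple[str, ...]) -> list[int]:
    """Positions of a label block within the full 66-attribute list."""
    return [ATTRIBUTES.index(a) for a in block]
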