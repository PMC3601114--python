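"""Canonical muscle channel ordering for the 16-channel lower-limb/trunk montage.

The ordering is fixed across the whole pipeline: readers, writers, the
synthetic generator and the co-contraction groups all index muscles by
position in :data:`MUSCLES`.
"""

from __future__ import annotations

MUSCLES: tuple[str, ...] = (
    "TA",   # tibialis anterior
    "PER",  # peroneus longus
    "SOL",  # soleus
    "GM",   # gastrocnemius medialis
    "VM",   # vastus medialis
    "VL",   # vastus lateralis
    "RF",   # rectus femoris
    "BF",   # biceps femoris (long head)
    "ST",   # semitendinosus
    "ADD",  # adductors
    "GME",  # gluteus medius
    "GMA",  # gluteus maximus
    "TFL",  # tensor fasciae latae
    "ESP",  # erector spinae (L1)
    "RAB",  # rectus abdominis
    "EOB",  # external oblique
)

#: knee flexor group used by the co-contraction ratio (hamstrings)
KNEE_FLEXORS: tuple[str, ...] = ("BF", "ST")
#: knee extensor group used by the co-contraction ratio (quadriceps)
KNEE_EXTENSORS: tuple[str, ...] = ("VM", "VL", "RF")


def muscle_index(label: str, labels: tuple[str, ...] | list[str] = MUSCLES) -> int:
    """Index of ``label`` in the channel ordering; raises ``KeyError`` if absent."""
    try:
        return list(labels).index(label)
    except ValueError as exc:
        raise KeyError(f"unknown muscle label {label!r}") from exc
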