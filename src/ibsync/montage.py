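"""32-channel montage and scalp-region grouping.

The recordings use a 32-electrode cap laid out on the extended international
10-20 system.  Channel order below is the acquisition order of the study-style
recordings; region grouping follows the five-region scheme used for
connectivity summaries (frontal, central, temporal, parietal, occipital).

The published central group lists C5, which does not exist in this montage,
while C4 is otherwise unassigned; the default map therefore uses {C3, Cz, C4}
and records the substitution in :data:`REGION_MAP_NOTES`.
"""

from __future__ import annotations

CHANNELS: tuple[str, ...] = (
    "Fp1", "Fz", "F3", "F7", "FT9", "FC5", "FC1", "C3", "T7", "TP9",
    "CP5", "CP1", "Pz", "P3", "P7", "O1", "Oz", "O2", "P4", "P8",
    "TP10", "CP6", "CP2", "Cz", "C4", "T8", "FT10", "FC6", "FC2", "F4",
    "F8", "Fp2",
)

N_CHANNELS = len(CHANNELS)

REGIONS: tuple[str, ...] = ("frontal", "central", "temporal", "parietal", "occipital")

REGION_MAP: dict[str, str] = {}
for _ch in ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6"):
    REGION_MAP[_ch] = "frontal"
for _ch in ("C3", "Cz", "C4"):
    REGION_MAP[_ch] = "central"
for _ch in ("FT9", "T7", "TP9", "FT10", "T8", "TP10"):
    REGION_MAP[_ch] = "temporal"
for _ch in ("CP5", "CP1", "CP6", "CP2", "P7", "P3", "Pz", "P4", "P8"):
    REGION_MAP[_ch] = "parietal"
for _ch in ("O1", "Oz", "O2"):
    REGION_MAP[_ch] = "occipital"

REGION_MAP_NOTES = (
    "central group uses C4 in place of the unavailable C5; "
    "TP9/TP10 are algebraically degenerate after mean-mastoid re-referencing"
)

assert set(REGION_MAP) == set(CHANNELS)


def channel_index(label: str) -> int:
    """Index of ``label`` in the canonical channel order."""
    try:
        return CHANNELS.index(label)
    except ValueError:
        raise KeyError(f"channel {label!r} not in montage") from None


def region_members(region: str) -> list[str]:
    if region not in REGIONS:
        raise KeyError(f"unknown region {region!r}")
    return [ch for ch in CHANNELS if REGION_MAP[ch] == region]
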