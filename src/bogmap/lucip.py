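"""Land Use Classification for Irish Peatlands (LUCIP) class schema.

Seven land-use classes describe the state of a raised bog surface: the two
peat-extraction classes (industrial *cutaway*, domestic *cutover*), the two
conversion classes (agricultural *grassland*, *forestry*), the uncut high-bog
*remnant peatland*, plus *water* bodies and *built-up* infrastructure.

Class codes 1-7 follow the schema order below; code 0 is reserved for
nodata / outside the peat mask.
"""

from __future__ import annotations

NODATA: int = 0

#: code -> name, in schema order (cutaway=1 ... built_up=7).
CLASS_NAMES: dict[int, str] = {
    1: "cutaway",
    2: "cutover",
    3: "grassland",
    4: "forestry",
    5: "remnant_peatland",
    6: "water",
    7: "built_up",
}

CLASS_CODES: dict[str, int] = {name: code for code, name in CLASS_NAMES.items()}

N_CLASSES: int = len(CLASS_NAMES)

#: Reflectance band order used throughout (Sentinel-2 style naming):
#: blue, green, red, three red-edge bands, NIR, narrow NIR, two SWIR bands.
BAND_NAMES: list[str] = ["B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8a", "B11", "B12"]

#: Full 12-feature stack order: the 10 reflectance bands then the two indices.
FEATURE_NAMES: list[str] = BAND_NAMES + ["NDVI", "NDWI"]

N_BANDS: int = len(BAND_NAMES)
N_FEATURES: int = len(FEATURE_NAMES)

#: Indices (into BAND_NAMES) of the visible and NIR bands used when stating
#: spectral-separability guarantees.
VISIBLE_NIR_BANDS: list[int] = [0, 1, 2, 6, 7]  # B2, B3, B4, B8, B8a
SWIR_BANDS: list[int] = [8, 9]  # B11, B12


def class_name(code: int) -> str:
    """Return the class name for ``code``, raising on unknown codes."""
    try:
        return CLASS_NAMES[int(code)]
    except KeyError:
        raise ValueError(f"unknown LUCIP class code: {code!r}") from None


def class_code(name_or_code: str | int) -> int:
    """Normalise a class name or code to the integer code."""
    if isinstance(name_or_code, str):
        try:
            return CLASS_CODES[name_or_code]
        except KeyError:
            raise ValueError(f"unknown LUCIP class name: {name_or_code!r}") from None
    code = int(name_or_code)
    if code not in CLASS_NAMES:
        raise ValueError(f"unknown LUCIP class code: {code!r}")
    return code
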