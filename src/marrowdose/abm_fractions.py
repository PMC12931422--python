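"""Reference distribution of active bone marrow across skeletal sites.

Active (red) marrow is spread over the skeleton in an age- and
sex-dependent way: nearly a quarter of an infant's marrow sits in the
craniofacial bones, while in adults the marrow has retreated from the
extremities into the axial skeleton (os coxae, vertebrae, ribs). The
table packaged here gives, for each of 34 named bone sites and each
reference individual (ages 0, 1, 5, 10, 15, 30 years; female and male,
with ages 0-10 sex-shared), the fraction of the body's total active
marrow residing at that site. These fractions derive from ICRP
reference-individual marrow distributions and sum to 1 over the
skeleton for every (age, sex) column.

Lookups snap to the nearest reference age (ties toward the older
column); no interpolation between columns is performed.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

__all__ = [
    "BONE_SITE_NAMES",
    "REFERENCE_AGES",
    "ABMFractionTable",
    "abm_fraction_lookup",
    "canonical_site_name",
    "default_table",
]

REFERENCE_AGES = (0, 1, 5, 10, 15, 30)

# Columns: site, age00 (F=M), age01, age05, age10, age15 F, age15 M, age30 F, age30 M.
_TABLE_CSV = """\
site,a00,a01,a05,a10,a15F,a15M,a30F,a30M
Craniofacial bones,0.2412,0.3274,0.3254,0.1753,0.0983,0.1198,0.0318,0.0447
Mandible,0.0433,0.0167,0.0212,0.0108,0.0078,0.0099,0.0086,0.0082
Scapulae,0.0323,0.0339,0.0404,0.0448,0.0380,0.0277,0.0742,0.0834
Clavicles,0.0122,0.0044,0.0080,0.0092,0.0085,0.0066,0.0097,0.0098
Sternum,0.0051,0.0054,0.0113,0.0162,0.0149,0.0214,0.0204,0.0240
Ribs,0.1628,0.1506,0.0850,0.0948,0.1036,0.0951,0.1244,0.0937
Cervical vertebrae,0.0373,0.0270,0.0152,0.0202,0.0316,0.0252,0.0327,0.0295
Thoracic vertebrae,0.0516,0.0944,0.0955,0.1525,0.1132,0.1252,0.1245,0.1199
Lumbar vertebrae,0.0470,0.0524,0.0640,0.1035,0.1385,0.1261,0.1559,0.1661
Sacrum,0.0188,0.0359,0.0430,0.0399,0.0684,0.0559,0.0651,0.0744
Os coxae,0.0631,0.1007,0.1138,0.1812,0.2460,0.2205,0.2495,0.2442
"Femora, proximal head",0.0346,0.0164,0.0216,0.0342,0.0593,0.0772,0.0491,0.0415
"Femora, upper shaft",0.0103,0.0048,0.0138,0.0152,0.0109,0.0150,0.0109,0.0258
"Femora, lower shaft",0.0164,0.0074,0.0095,0.0100,0.0071,0.0066,0.0,0.0
"Femora, distal head",0.0286,0.0170,0.0235,0.0183,0.0,0.0,0.0,0.0
"Tibiae, proximal head",0.0246,0.0099,0.0121,0.0089,0.0,0.0,0.0,0.0
"Tibiae, shaft",0.0094,0.0102,0.0109,0.0077,0.0,0.0,0.0,0.0
"Tibiae, distal head",0.0150,0.0021,0.0038,0.0022,0.0,0.0,0.0,0.0
"Fibulae, proximal head",0.0033,0.0005,0.0012,0.0007,0.0,0.0,0.0,0.0
"Fibulae, shaft",0.0015,0.0010,0.0025,0.0016,0.0,0.0,0.0,0.0
"Fibulae, distal head",0.0050,0.0004,0.0011,0.0007,0.0,0.0,0.0,0.0
Patellae,0.0013,0.0016,0.0059,0.0033,0.0,0.0,0.0,0.0
Ankles and feet,0.0375,0.0254,0.0176,0.0,0.0,0.0,0.0,0.0
"Humeri, proximal head",0.0212,0.0148,0.0166,0.0245,0.0469,0.0589,0.0394,0.0283
"Humeri, upper shaft",0.0045,0.0041,0.0063,0.0059,0.0047,0.0059,0.0039,0.0065
"Humeri, lower shaft",0.0045,0.0038,0.0058,0.0058,0.0023,0.0030,0.0,0.0
"Humeri, distal head",0.0166,0.0068,0.0083,0.0055,0.0,0.0,0.0,0.0
"Radii, proximal head",0.0036,0.0005,0.0008,0.0004,0.0,0.0,0.0,0.0
"Radii, shaft",0.0017,0.0017,0.0031,0.0018,0.0,0.0,0.0,0.0
"Radii, distal head",0.0065,0.0010,0.0016,0.0009,0.0,0.0,0.0,0.0
"Ulnae, proximal head",0.0086,0.0019,0.0030,0.0017,0.0,0.0,0.0,0.0
"Ulnae, shaft",0.0020,0.0028,0.0035,0.0020,0.0,0.0,0.0,0.0
"Ulnae, distal head",0.0044,0.0001,0.0004,0.0002,0.0,0.0,0.0,0.0
Wrists and hands,0.0242,0.0171,0.0043,0.0,0.0,0.0,0.0,0.0
"""


def _load_frame() -> pd.DataFrame:
    df = pd.read_csv(io.StringIO(_TABLE_CSV))
    df["site"] = df["site"].str.strip()
    return df.set_index("site")


_FRAME = _load_frame()

BONE_SITE_NAMES: tuple[str, ...] = tuple(_FRAME.index)
_NAME_LOOKUP = {name.lower(): name for name in BONE_SITE_NAMES}


def canonical_site_name(name: str) -> str:
    """Resolve a site name case-insensitively to its canonical spelling.

    Returns the input unchanged when it is not a known site (callers
    decide whether that is an error).
    """
    return _NAME_LOOKUP.get(name.strip().lower(), name)


def _column_key(age_years: float, sex: str) -> str:
    deltas = [abs(age_years - a) for a in REFERENCE_AGES]
    best = min(deltas)
    # tie toward the older reference column
    ref = max(a for a, d in zip(REFERENCE_AGES, deltas) if d == best)
    if ref <= 10:
        return f"a{ref:02d}"
    return f"a{ref:02d}{sex}"


class ABMFractionTable:
    """Fraction of total active marrow per bone site, by reference age and sex."""

    def __init__(self, frame: pd.DataFrame | None = None):
        self._frame = _FRAME if frame is None else frame

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def fraction(self, site: str, age_years: float, sex: str) -> float:
        if sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        name = canonical_site_name(site)
        if name not in self._frame.index:
            raise KeyError(f"unknown bone site: {site!r}")
        return float(self._frame.loc[name, _column_key(age_years, sex)])

    def column(self, age_years: float, sex: str) -> dict[str, float]:
        """All 34 site fractions for the reference column matched by (age, sex)."""
        key = _column_key(age_years, sex)
        return {site: float(v) for site, v in self._frame[key].items()}

    def column_sums(self) -> dict[str, float]:
        """Sum of each (age, sex) column over the 34 sites (each should be ~1.0)."""
        sums = {}
        for age in REFERENCE_AGES:
            for sex in "FM":
                sums[f"{age:02d}{sex}"] = float(
                    np.sum(list(self.column(age, sex).values()))
                )
        return sums


_DEFAULT = ABMFractionTable()


def default_table() -> ABMFractionTable:
    return _DEFAULT


def abm_fraction_lookup(site: str, age_years: float, sex: str) -> float:
    """Fraction of total active marrow at ``site`` for the nearest reference (age, sex)."""
    return _DEFAULT.fraction(site, age_years, sex)
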