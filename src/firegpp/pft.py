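"""Plant-functional-type parameters: photosynthesis, conductance, ozone damage.

The eight PFTs mirror the usual dynamic-vegetation-model classification.
Photosynthetic and Ball-Berry constants are standard literature values.
The ozone damage coefficients ``a_low``/``a_high`` bracket the tolerance
spread of species within a PFT; the shipped values were produced by the
calibration routine in :mod:`firegpp.calibrate`, which scales the
flux-damage coefficients so the modelled percent-GPP-per-ppbv response of
deciduous broadleaf forest matches observed GPP-O3 relationships.  The
flux thresholds are 1.6 nmol m-2 s-1 for woody PFTs and 5 nmol m-2 s-1
for herbaceous ones, as in the flux-based damage literature.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import pandas as pd

__all__ = ["PFTParams", "load_pft_table", "get_pft", "PFT_NAMES"]

PFT_NAMES = (
    "evergreen_needleleaf_forest",
    "deciduous_broadleaf_forest",
    "evergreen_broadleaf_forest",
    "shrubland",
    "tundra",
    "c3_grass",
    "c4_grass",
    "c3_crop",
)

FOREST_PFTS = (
    "evergreen_needleleaf_forest",
    "deciduous_broadleaf_forest",
    "evergreen_broadleaf_forest",
)


@dataclass(frozen=True)
class PFTParams:
    pft_name: str
    pathway: str                 # "C3" | "C4"
    vcmax25: float               # umol m-2 s-1
    jmax_ratio: float            # Jmax25 / Vcmax25
    ball_berry_slope: float      # dimensionless m
    ball_berry_intercept: float  # mol m-2 s-1
    a_low: float                 # damage sensitivity, (nmol m-2 s-1)-1
    a_high: float
    t_o3: float                  # damage flux threshold, nmol m-2 s-1

    def __post_init__(self):
        if self.vcmax25 <= 0:
            raise ValueError("vcmax25 must be positive")
        if self.ball_berry_slope <= 0:
            raise ValueError("Ball-Berry slope must be positive")
        if self.a_low > self.a_high:
            raise ValueError("a_low must not exceed a_high")
        if self.t_o3 < 0:
            raise ValueError("t_o3 must be non-negative")
        if self.pathway not in ("C3", "C4"):
            raise ValueError(f"unknown pathway {self.pathway!r}")

    @property
    def a_mean(self) -> float:
        return 0.5 * (self.a_low + self.a_high)

    def damage_coefficient(self, sensitivity: str) -> float:
        try:
            return {"low": self.a_low, "high": self.a_high, "mean": self.a_mean}[sensitivity]
        except KeyError:
            raise ValueError(f"sensitivity must be low|high|mean, got {sensitivity!r}")

    def with_scaled_damage(self, factor: float) -> "PFTParams":
        """Copy with ozone damage coefficients scaled by ``factor``."""
        return replace(self, a_low=self.a_low * factor, a_high=self.a_high * factor)


def load_pft_table(path=None) -> dict:
    """Load the PFT parameter table (package CSV by default)."""
    if path is None:
        with resources.files("firegpp").joinpath("data/pft_params.csv").open() as fh:
            df = pd.read_csv(fh, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    required = {
        "pft_name", "pathway", "vcmax25", "jmax_ratio", "ball_berry_slope",
        "ball_berry_intercept", "a_low", "a_high", "t_o3",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"PFT table missing columns: {sorted(missing)}")
    return {
        row.pft_name: PFTParams(
            pft_name=row.pft_name,
            pathway=row.pathway,
            vcmax25=row.vcmax25,
            jmax_ratio=row.jmax_ratio,
            ball_berry_slope=row.ball_berry_slope,
            ball_berry_intercept=row.ball_berry_intercept,
            a_low=row.a_low,
            a_high=row.a_high,
            t_o3=row.t_o3,
        )
        for row in df.itertuples()
    }


def get_pft(name: str, path=None) -> PFTParams:
    table = load_pft_table(path)
    if name not in table:
        raise KeyError(f"unknown PFT {name!r}; known: {sorted(table)}")
    return table[name]
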