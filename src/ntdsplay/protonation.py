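"""Proton-occupancy arithmetic for titratable sites.

pKa values and burial fractions come from external structure-based
predictors and are consumed as inputs (CSV); the only computation here
is the Henderson-Hasselbalch protonated fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["TitratableSite", "protonated_fraction", "read_sites_csv"]


@dataclass
class TitratableSite:
    """A titratable residue: label, predicted pKa, solvent burial fraction."""

    label: str
    pKa: float
    burial_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.burial_fraction <= 1.0:
            raise ValueError("burial_fraction must be in [0, 1]")


def protonated_fraction(site: TitratableSite, pH: float) -> float:
    """Henderson-Hasselbalch protonated fraction f = 1/(1 + 10^(pH - pKa)).

    f = 0.5 at pH = pKa and changes 10-fold per pH unit on either side.
    """
    return 1.0 / (1.0 + 10.0 ** (pH - site.pKa))


def read_sites_csv(path) -> list:
    """Read sites from CSV columns ``label,pKa,burial``."""
    df = pd.read_csv(path)
    burial = df["burial"] if "burial" in df else 0.0 * df["pKa"]
    return [
        TitratableSite(str(row.label), float(row.pKa), float(b))
        for (_, row), b in zip(df.iterrows(), burial)
    ]
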