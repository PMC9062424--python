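"""Beer-Lambert conversions for the colorimetric/UV quantifications
(ferrozine-iron at 562 nm, methylene-blue sulfide at 670 nm, peptide A280)
and molar-equivalents arithmetic. Units are mM and cm throughout."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

# published molar extinction coefficients, mM^-1 cm^-1
EPSILON_FERROZINE_562 = 27.9
EPSILON_METHYLENE_BLUE_670 = 34.5
EPSILON_PEPTIDE_280 = 5.6


@dataclass(frozen=True)
class AssaySample:
    absorbance: float
    epsilon: float  # mM^-1 cm^-1
    path_cm: float = 1.0
    dilution_factor: float = 1.0
    reference_conc: Optional[float] = None  # mM, for equivalents
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.absorbance < 0:
            raise ValueError("negative absorbance")
        if self.epsilon <= 0 or self.path_cm <= 0:
            raise ValueError("epsilon and path length must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")


def concentration(sample: AssaySample) -> float:
    """Analyte concentration in mM: A / (epsilon * l) * dilution."""
    return sample.absorbance / (sample.epsilon * sample.path_cm) * sample.dilution_factor


def equivalents(analyte_mM: float, reference_mM: float) -> float:
    """Molar equivalents of analyte per reference (e.g. Fe per monomer)."""
    if reference_mM <= 0:
        raise ValueError("reference concentration must be positive")
    return analyte_mM / reference_mM


def read_assay_csv(path) -> list[AssaySample]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            AssaySample(
                sample_id=str(row.get("sample_id", "")),
                absorbance=float(row["absorbance"]),
                epsilon=float(row["epsilon"]),
                path_cm=float(row.get("path_cm", 1.0)),
                dilution_factor=float(row.get("dilution_factor", 1.0)),
                reference_conc=(
                    float(row["reference_conc"]) if "reference_conc" in row and pd.notna(row["reference_conc"]) else None
                ),
            )
        )
    return out


def write_assay_csv(samples: list[AssaySample], path) -> pd.DataFrame:
    rows = []
    for s in samples:
        conc = concentration(s)
        rows.append(
            {
                "sample_id": s.sample_id,
                "absorbance": s.absorbance,
                "epsilon": s.epsilon,
                "path_cm": s.path_cm,
                "dilution_factor": s.dilution_factor,
                "concentration_mM": conc,
                "equivalents": (
                    equivalents(conc, s.reference_conc)
                    if s.reference_conc is not None
                    else None
                ),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
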