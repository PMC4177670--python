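"""Kinetic parameters of the lac operon model.

The model tracks intracellular lactose (L), allolactose (A), lac mRNA (M) and
LacZ protein (B), all in nM, with time in minutes.  LacY permease levels are
assumed proportional to LacZ levels, so a single protein variable drives both
import and catalysis.

Two quantities are *derived* rather than free:

* the basal transcription fraction ``B0 / Bmax`` -- so that the uninduced
  fixed point of the protein equation is exactly the basal level ``B0``;
* the lumped translation rate ``k_B = mu * gammaM * Bmax / alphaM`` -- so that
  the fully induced fixed point is exactly ``Bmax``.

This closure anchors the model to the two measured expression levels
(34.2 nM basal, 34,286 nM induced) independently of the mRNA scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants and concentrations of the four-variable lac model.

    Units: rates in 1/min, concentrations and Michaelis constants in nM,
    ``mrna_transcription_rate`` in nM/min.  Defaults correspond to a 60-minute
    generation time in minimal medium.
    """

    #: dilution rate mu; ln(2)/60 corresponds to a 60-min generation time
    growth_rate: float = math.log(2.0) / 60.0
    #: permease import turnover number (per LacY-equivalent, 1/min)
    permease_import_turnover: float = 2400.0
    #: beta-gal lactose turnover number (1/min)
    bgal_lactose_turnover: float = 600.0
    #: fraction of beta-gal lactose conversion branched into allolactose
    lactose_to_allolactose_branching: float = 0.448
    #: beta-gal allolactose turnover number (1/min)
    bgal_allolactose_turnover: float = 25.0
    #: basal beta-gal level (nM)
    basal_bgal_level: float = 34.2
    #: fully induced beta-gal level (nM)
    induced_bgal_level: float = 34286.0
    #: external lactose concentration during lactose phases (nM)
    external_lactose: float = 11700.0
    #: permease Michaelis constant for external lactose (nM)
    permease_Km: float = 5.0e5
    #: beta-gal Michaelis constant for lactose (nM)
    bgal_lactose_Km: float = 2530.0
    #: beta-gal Michaelis constant for allolactose (nM)
    bgal_allolactose_Km: float = 1200.0
    #: allolactose level giving half-maximal lac induction (nM)
    half_max_induction: float = 1.0e3
    #: maximal mRNA transcription rate (nM/min)
    mrna_transcription_rate: float = 20.0
    #: first-order mRNA loss rate (1/min); 1/1.5 min lac mRNA lifetime
    mrna_degradation_rate: float = 1.0 / 1.5
    #: Hill coefficient for lac induction by allolactose
    hill_number: float = 2.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{f.name} must be finite and non-negative, got {v}")
        if not 0.0 <= self.lactose_to_allolactose_branching <= 1.0:
            raise ValueError("branching ratio phi must lie in [0, 1]")
        if self.hill_number < 1.0:
            raise ValueError("Hill number must be >= 1")
        if self.basal_bgal_level >= self.induced_bgal_level:
            raise ValueError("basal level must be below the induced level")

    # -- derived quantities --------------------------------------------------

    @property
    def generation_time(self) -> float:
        """Population doubling time ln(2)/mu in minutes."""
        return math.log(2.0) / self.growth_rate

    @property
    def basal_fraction(self) -> float:
        """Basal transcription as a fraction of maximal transcription."""
        return self.basal_bgal_level / self.induced_bgal_level

    @property
    def translation_rate(self) -> float:
        """Lumped protein production rate per mRNA (1/min), closed so the
        induced fixed point equals ``induced_bgal_level``.

        With transcription switched off entirely the closure is indeterminate
        and protein production is impossible asymptotically; 0 is returned.
        """
        if self.mrna_transcription_rate == 0.0:
            return 0.0
        return (
            self.growth_rate
            * self.mrna_degradation_rate
            * self.induced_bgal_level
            / self.mrna_transcription_rate
        )

    def with_(self, **kwargs) -> "ModelParameters":
        """Return a copy with selected fields replaced."""
        return replace(self, **kwargs)

    # -- flat key/value config I/O -------------------------------------------

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)!r}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParameters":
        return cls(**_parse_flat_config(Path(path).read_text()))

    @classmethod
    def table_defaults(cls) -> "ModelParameters":
        """Defaults as shipped in the packaged parameter file."""
        text = (
            resources.files("lacmem").joinpath("data/lac_parameters.cfg").read_text()
        )
        return cls(**_parse_flat_config(text))


def _parse_flat_config(text: str) -> dict:
    valid = {f.name for f in fields(ModelParameters)}
    out: dict = {}
    for ln in text.splitlines():
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        if "=" not in ln:
            raise ValueError(f"bad config line: {ln!r}")
        key, val = (s.strip() for s in ln.split("=", 1))
        if key not in valid:
            raise ValueError(f"unknown parameter {key!r}")
        out[key] = float(val)
    return out
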