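"""Exposure-study dose design.

The design fixes everything downstream model fitting needs to know about the
in-vivo study: the administered dose levels (mg/kg body weight per day), the
number of animals per dose group, and how many pooled-QC injections and
extraction blanks accompany the biological samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class DoseDesign:
    """Dose levels and replicate structure of a dose-response study.

    Parameters
    ----------
    doses
        Strictly increasing dose levels in mg/kg; the first element must be 0
        (vehicle control).
    replicates
        Number of animals per dose group, aligned with ``doses``.
    qc_count
        Number of pooled intrastudy-QC injections per assay.
    blank_count
        Number of extraction blanks per assay.
    """

    doses: tuple[float, ...]
    replicates: tuple[int, ...]
    qc_count: int = 8
    blank_count: int = 3

    def __post_init__(self) -> None:
        doses = tuple(float(d) for d in self.doses)
        reps = tuple(int(r) for r in self.replicates)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "replicates", reps)
        if len(doses) != len(reps):
            raise ValueError("doses and replicates must have equal length")
        if not doses or doses[0] != 0.0:
            raise ValueError("first dose must be 0 (vehicle control)")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("doses must be strictly increasing")
        if sum(d == 0.0 for d in doses) != 1:
            raise ValueError("exactly one zero dose required")
        if any(r < 1 for r in reps):
            raise ValueError("all replicate counts must be >= 1")
        if len(doses) - 1 < 3:
            raise ValueError("at least 3 distinct nonzero doses are required")
        if self.qc_count < 0 or self.blank_count < 0:
            raise ValueError("qc_count and blank_count must be >= 0")

    @property
    def n_study_samples(self) -> int:
        return sum(self.replicates)

    @property
    def lowest_nonzero_dose(self) -> float:
        return self.doses[1]

    @property
    def highest_dose(self) -> float:
        return self.doses[-1]

    @property
    def censoring_cutoff(self) -> float:
        """Lower limit of extrapolation: lowest nonzero dose / 3, one decimal.

        BMD estimates below this dose cannot be supported by the tested dose
        range and are reported only as "< cutoff".
        """
        return round(self.lowest_nonzero_dose / 3.0, 1)

    def sample_doses(self) -> list[float]:
        """Per-animal dose vector, group order, controls first."""
        out: list[float] = []
        for d, r in zip(self.doses, self.replicates):
            out.extend([d] * r)
        return out


#: The rat TPhP gavage study layout: doses 0-881 mg/kg, three animals per
#: group except two at 441 mg/kg (17 study samples in total).
DEFAULT_DESIGN = DoseDesign(
    doses=(0.0, 55.0, 110.0, 220.0, 441.0, 881.0),
    replicates=(3, 3, 3, 3, 2, 3),
)
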