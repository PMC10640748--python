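"""Two-step MR mediation: indirect effects and proportion mediated.

The indirect effect of an exposure on the outcome through a mediator is the
product of the exposure->mediator effect (step 1) and the mediator->outcome
MR estimate (step 2); the proportion mediated divides it by the total
exposure->outcome effect. All arithmetic stays on the beta (log-risk)
scale. A mediator whose indirect effect points against the total effect is
labelled inconsistent and no proportion is reported for it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .mr_core import MREstimate

logger = logging.getLogger(__name__)

INCONSISTENT_LABEL = "Effect not consistent"


class UndefinedProportionError(ValueError):
    """The total effect is zero; no proportion mediated exists."""


@dataclass(frozen=True)
class MediationResult:
    """Decomposition of a total effect through one mediator."""

    total: MREstimate
    step1_beta: float
    step1_se: float
    step2: MREstimate
    indirect: float
    indirect_se: float
    proportion_pct: float | None
    consistent: bool

    @property
    def label(self) -> str:
        return "" if self.consistent else INCONSISTENT_LABEL


def two_step_mediation(
    total: MREstimate,
    step1_beta: float,
    step1_se: float,
    step2: MREstimate,
) -> MediationResult:
    """Product-of-coefficients mediation through a single mediator.

    ``indirect = step1_beta * step2.beta`` with a product delta-method SE;
    ``proportion_pct = 100 * indirect / total.beta`` when the indirect and
    total effects agree in direction (an indirect effect of exactly zero
    counts as consistent, mediating 0%). Proportions outside [0, 100]% are
    reported verbatim with a warning.
    """
    if total.beta == 0:
        raise UndefinedProportionError("total effect is zero; proportion mediated undefined")
    indirect = step1_beta * step2.beta
    indirect_se = math.sqrt(
        step1_beta**2 * step2.se**2 + step2.beta**2 * step1_se**2
    )
    consistent = indirect * total.beta >= 0
    proportion = 100.0 * indirect / total.beta if consistent else None
    if proportion is not None and not (0.0 <= proportion <= 100.0):
        logger.warning(
            "proportion mediated %.2f%% outside [0, 100]%% (weak total effect?)",
            proportion,
        )
    return MediationResult(
        total=total,
        step1_beta=step1_beta,
        step1_se=step1_se,
        step2=step2,
        indirect=indirect,
        indirect_se=indirect_se,
        proportion_pct=proportion,
        consistent=consistent,
    )
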