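"""Partitioned survival engine: state occupancy read directly off the PFS
and OS curves (PD share = area between them)."""

from __future__ import annotations

import logging

import numpy as np

from .cohort import ModelSettings, Occupancy
from .survival import ParametricSurvival

logger = logging.getLogger(__name__)


def compute_occupancy_psm(
    pfs: ParametricSurvival,
    os: ParametricSurvival,
    settings: ModelSettings,
) -> Occupancy:
    """Occupancy at each cycle boundary t_k:

    share_pfs = min(S_PFS(t_k), S_OS(t_k))
    share_pd  = S_OS(t_k) - share_pfs
    share_dead = 1 - S_OS(t_k)

    Independently fitted curves can cross; the PFS share is capped at OS
    and the number of capped boundaries is logged.
    """
    t = settings.boundary_times_months()
    s_pfs = np.asarray(pfs.sf(t), dtype=float)
    s_os = np.asarray(os.sf(t), dtype=float)
    crossed = int(np.sum(s_pfs > s_os + 1e-12))
    if crossed:
        logger.warning(
            "PFS curve exceeds OS curve at %d cycle boundaries; capped", crossed
        )
    share_pfs = np.minimum(s_pfs, s_os)
    return Occupancy(t, share_pfs, s_os - share_pfs, 1.0 - s_os)
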