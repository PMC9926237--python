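"""Sample-level quality control by total UMI count.

Low-quality libraries are dropped by total molecule count: fewer than 256
UMIs (empty or degraded wells) or more than 2^17 (multiplets / barcode
collisions).  Both boundary values are retained — the bounds read "less
than" and "over".  The same rule is applied to single cells and PICs.
"""

from __future__ import annotations

import logging

import numpy as np

from .data_model import CountMatrix

logger = logging.getLogger("picseq")

LOWER_UMI_DEFAULT = 256
UPPER_UMI_DEFAULT = 2 ** 17  # 131072


def filter_by_umi(
    m: CountMatrix,
    lower: int = LOWER_UMI_DEFAULT,
    upper: int = UPPER_UMI_DEFAULT,
) -> CountMatrix:
    """Retain exactly the samples with ``lower <= total UMI <= upper``.

    Gene set and sample order are unchanged; an empty result is allowed and
    logged.
    """
    if lower < 0 or upper < lower:
        raise ValueError(f"bad UMI bounds: lower={lower}, upper={upper}")
    totals = m.totals()
    keep = (totals >= lower) & (totals <= upper)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("UMI filter dropped %d of %d samples", n_drop, m.n_samples)
    if not keep.any():
        logger.warning("UMI filter removed every sample")
    return m.subset_samples(np.asarray(keep))
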