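"""Head-size normalisation of regional brain volumes.

Regional volumes are expressed relative to intracranial volume (ICV) to
remove between-subject differences in head size; the denominator can be
switched to total brain volume (TBV).
"""

from __future__ import annotations

import pandas as pd

from .config import REGIONS


def relative_volumes(
    volumes: pd.DataFrame, denominator: str = "icv"
) -> pd.DataFrame:
    """Add ``rel_<region>`` columns: each regional volume / ICV (or TBV).

    Parameters
    ----------
    volumes:
        Table with ``subject_id``, ``icv``, ``tbv`` and one column per region
        (absolute mm3).
    denominator:
        ``"icv"`` (default) or ``"tbv"``.
    """
    if denominator not in ("icv", "tbv"):
        raise ValueError("denominator must be 'icv' or 'tbv'")
    denom = volumes[denominator]
    if (denom <= 0).any():
        raise ValueError(f"non-positive {denominator} encountered")
    out = volumes.copy()
    for region in REGIONS:
        out[f"rel_{region}"] = volumes[region] / denom
    return out
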