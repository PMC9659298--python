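"""Packaged reference tables: the coded effect-size table and the
normalized coefficient table, hand-transcribed from the published study."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core import CoefficientSet
from .meta import EffectSizeRecord

__all__ = ["load_builtin_fixture", "FIXTURES"]

FIXTURES = ("table1_effects", "table2_coefficients")


def _read(name: str) -> pd.DataFrame:
    with resources.files("dualsafe.data").joinpath(f"{name}.csv").open("r") as fh:
        return pd.read_csv(fh)


def load_builtin_fixture(name: str):
    """Load a packaged table by name.

    ``table1_effects`` returns the coded per-study correlations as a list of
    :class:`~dualsafe.meta.EffectSizeRecord` (total N per path split as
    evenly as possible across its studies, remainder on the last studies);
    ``table2_coefficients`` returns the normalized coefficients as a
    validated :class:`~dualsafe.core.CoefficientSet`.
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; available: {FIXTURES}")
    df = _read(name)
    if name == "table1_effects":
        return [
            EffectSizeRecord(
                path_id=row.path_id,
                study_id=row.study_id,
                n=int(row.n),
                effect_kind=row.effect_kind,
                effect_value=float(row.effect_value),
                df=None if pd.isna(row.df) else float(row.df),
            )
            for row in df.itertuples(index=False)
        ]
    return CoefficientSet(dict(zip(df["path_id"], df["coefficient"].astype(float))))
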