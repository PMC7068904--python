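"""Packaged data: the nine-run response table of the reference study.

The fixture maps each L9 run of the implantation-angle design (varus,
posterior-slope cut, external rotation) to the finite-element peak contact
pressure on the polyethylene liner under a 1150 N axial load at 0 deg
flexion.  These responses are consumed as data — the package's surrogate
does not recompute them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["table3_responses_path", "load_table3_responses"]


def table3_responses_path() -> str:
    """Filesystem path of the packaged nine-run response fixture."""
    return str(resources.files("tkaopt.data") / "table3_responses.csv")


def load_table3_responses() -> pd.DataFrame:
    """The packaged response table (run_id, combination, angles, response)."""
    return pd.read_csv(table3_responses_path())
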