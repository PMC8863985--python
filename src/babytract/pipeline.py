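"""In-memory convenience pipeline: phantom/session data -> profile tables.

The CLI wires the same stages through files; these helpers keep everything
in memory for scripted analyses and tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import PROFILE_COLUMNS
from .phantom import PhantomData
from .profiles import compute_profile
from .segmentation import SegmentedBundle

__all__ = ["grand_mean_by_timepoint", "profile_phantom_sessions"]


def profile_phantom_sessions(data: PhantomData,
                             bundles: dict[str, SegmentedBundle],
                             metric: str = "r1",
                             weighting: str = "gaussian",
                             n_nodes: int = 100) -> pd.DataFrame:
    """Profile every session of a phantom cohort -> long-format table.

    The ventricle-analog mask is applied to each volume before sampling
    (strict mode), exactly as the CLI pipeline does.
    """
    frames = []
    for sess in data.sessions:
        vol = sess.r1 if metric == "r1" else sess.md
        if vol is None:
            raise ValueError(f"phantom has no {metric} volumes")
        vol = vol.mask_out(data.ventricle_mask)
        rows = []
        for name in sorted(bundles):
            p = compute_profile(data.streamlines, bundles[name], vol,
                                weighting=weighting, n_nodes=n_nodes,
                                metric=metric)
            for k in range(p.n_nodes):
                rows.append((sess.meta.subject_id, sess.meta.age_days,
                             sess.meta.timepoint, p.bundle, k + 1, metric,
                             p.value_mean[k], *p.core_xyz[k]))
        frames.append(pd.DataFrame(rows, columns=PROFILE_COLUMNS))
    return pd.concat(frames, ignore_index=True)


def grand_mean_by_timepoint(profile_table: pd.DataFrame, metric: str
                            ) -> pd.Series:
    """Grand mean of bundle-mean values per timepoint.

    Bundle means are taken over nodes within each session, then averaged
    over bundles and subjects with equal bundle weight.
    """
    t = profile_table[profile_table["metric"] == metric].dropna(subset=["value"])
    session_bundle = t.groupby(["timepoint", "subject", "bundle"])["value"].mean()
    return session_bundle.groupby("timepoint").mean()
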