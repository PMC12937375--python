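"""Cross-variant statistics on per-replica contact durations.

Two duration atlases (same detector parameters, same window) are
compared pair by pair with a two-sided Welch t-test on the per-replica
cumulative durations, zero-filled to the replica count, so a contact
absent from one variant is tested against an all-zero sample when it
survives filtering in the other it is reported as unique instead. No
multiplicity correction is applied; the number of tests performed is
reported so users can post-correct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .persistence import DurationAtlas, PairKey

__all__ = ["WelchResult", "DifferentialContact", "welch_test", "compare_atlases"]


@dataclass(frozen=True)
class WelchResult:
    t_stat: float
    df: float
    p_value: float
    n_a: int
    n_b: int
    degenerate: bool = False


@dataclass
class DifferentialContact:
    key: PairKey
    layer: str
    mean_a_ns: float
    mean_b_ns: float
    delta_ns: float  # mean_a - mean_b
    welch: Optional[WelchResult]
    status: str  # shared | unique_to_a | unique_to_b
    significant: bool


def welch_test(sample_a, sample_b) -> WelchResult:
    """Two-sided Welch t-test (unequal variances).

    t = (x̄_a − x̄_b) / √(s²_a/n_a + s²_b/n_b) with Welch–Satterthwaite
    degrees of freedom; p from the Student t distribution. Degenerate
    zero-variance cases: equal means → t=0, p=1; different means → p=0,
    flagged.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a < 2 or n_b < 2:
        raise ValueError(f"welch_test needs n >= 2 per sample, got {n_a} and {n_b}")
    va = float(np.var(a, ddof=1))
    vb = float(np.var(b, ddof=1))
    ma, mb = float(a.mean()), float(b.mean())
    if va == 0.0 and vb == 0.0:
        if ma == mb:
            return WelchResult(0.0, float("inf"), 1.0, n_a, n_b, degenerate=True)
        return WelchResult(math.copysign(math.inf, ma - mb), float("inf"), 0.0, n_a, n_b, degenerate=True)
    se2 = va / n_a + vb / n_b
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    p = min(p, 1.0)
    return WelchResult(t, df, p, n_a, n_b)


def compare_atlases(
    atlas_a: DurationAtlas, atlas_b: DurationAtlas, alpha: float = 0.05
) -> list[DifferentialContact]:
    """Differential contacts between two complexes, sorted by |delta| desc.

    Rejects like-for-like violations: the two atlases must share detector
    parameters and window length. Shared pairs get a Welch test on the
    zero-filled per-replica durations; pairs present in one atlas only
    are labelled unique without a test.
    """
    _check_comparable(atlas_a, atlas_b)
    out: list[DifferentialContact] = []
    keys = set(atlas_a.records) | set(atlas_b.records)
    for key in sorted(keys):
        ra = atlas_a.records.get(key)
        rb = atlas_b.records.get(key)
        if ra is not None and rb is not None:
            w = welch_test(ra.per_replica_duration_ns, rb.per_replica_duration_ns)
            out.append(
                DifferentialContact(
                    key=key,
                    layer=f"{ra.layer.kind}/{ra.layer.span}",
                    mean_a_ns=ra.mean_duration_ns,
                    mean_b_ns=rb.mean_duration_ns,
                    delta_ns=ra.mean_duration_ns - rb.mean_duration_ns,
                    welch=w,
                    status="shared",
                    significant=bool(w.p_value < alpha),
                )
            )
        elif ra is not None:
            out.append(
                DifferentialContact(
                    key=key,
                    layer=f"{ra.layer.kind}/{ra.layer.span}",
                    mean_a_ns=ra.mean_duration_ns,
                    mean_b_ns=0.0,
                    delta_ns=ra.mean_duration_ns,
                    welch=None,
                    status="unique_to_a",
                    significant=False,
                )
            )
        else:
            assert rb is not None
            out.append(
                DifferentialContact(
                    key=key,
                    layer=f"{rb.layer.kind}/{rb.layer.span}",
                    mean_a_ns=0.0,
                    mean_b_ns=rb.mean_duration_ns,
                    delta_ns=-rb.mean_duration_ns,
                    welch=None,
                    status="unique_to_b",
                    significant=False,
                )
            )
    out.sort(key=lambda d: (-abs(d.delta_ns), d.key))
    return out


def _check_comparable(a: DurationAtlas, b: DurationAtlas) -> None:
    if not math.isclose(a.window_length_ns, b.window_length_ns):
        raise ValueError(
            f"window length mismatch: {a.window_length_ns} vs {b.window_length_ns} ns"
        )
    keys = set(a.parameters) | set(b.parameters)
    for k in sorted(keys):
        if a.parameters.get(k) != b.parameters.get(k):
            raise ValueError(
                f"detector parameter mismatch for {k!r}: "
                f"{a.parameters.get(k)} vs {b.parameters.get(k)}"
            )


def differential_dataframe(diffs: list[DifferentialContact]):
    import pandas as pd

    rows = []
    for d in diffs:
        rows.append(
            {
                "chain_a": d.key.chain_a,
                "res_a": d.key.res_a,
                "chain_b": d.key.chain_b,
                "res_b": d.key.res_b,
                "type": d.key.itype,
                "layer": d.layer,
                "mean_a_ns": d.mean_a_ns,
                "mean_b_ns": d.mean_b_ns,
                "delta_ns": d.delta_ns,
                "t": d.welch.t_stat if d.welch else float("nan"),
                "df": d.welch.df if d.welch else float("nan"),
                "p": d.welch.p_value if d.welch else float("nan"),
                "status": d.status,
                "significant": d.significant,
            }
        )
    return pd.DataFrame(rows)
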