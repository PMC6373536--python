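"""Posterior-predictive model-fit checks.

Simulate RT sets from each fitted (v, a, ter) cell estimate and compare
observed against predicted medians and tail percentiles, separately for
correct and error responses. With a symmetric start the model predicts
identical correct- and error-RT shapes, so a worse error-stream fit is an
expected, reported property rather than a bug.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .wiener import simulate_first_passage

__all__ = ["posterior_predict", "fit_summary", "plot_fit"]

CELL_KEYS = [
    "participant_id",
    "participant_gender",
    "expression",
    "required_response",
    "face_gender",
]

_CHUNK = 1_000_000  # simulated trials per vectorised batch


def posterior_predict(
    estimates: pd.DataFrame,
    n_sim: int = 10_000,
    seed: int = 0,
    dt: float = 5e-4,
) -> pd.DataFrame:
    """Simulate ``n_sim`` diffusion trials from every non-degenerate estimate.

    Returns a long DataFrame (cell keys + ``rt_ms`` + ``correct``); cells
    flagged degenerate are skipped and counted in ``result.attrs["skipped"]``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    usable = estimates[~estimates["degenerate"].astype(bool)].reset_index(drop=True)
    skipped = len(estimates) - len(usable)

    v = np.repeat(usable["v"].to_numpy(dtype=float), n_sim)
    a = np.repeat(usable["a"].to_numpy(dtype=float), n_sim)
    # negative flagged ter estimates would produce impossible RTs; floor at 0
    ter = np.repeat(np.clip(usable["ter"].to_numpy(dtype=float), 0.0, None), n_sim)
    s = float(usable["s"].iloc[0]) if len(usable) else 1.0

    rts = np.empty(v.size)
    upper = np.empty(v.size, dtype=bool)
    for start in range(0, v.size, _CHUNK):
        sl = slice(start, min(start + _CHUNK, v.size))
        rts[sl], upper[sl] = simulate_first_passage(
            v[sl], a[sl], ter[sl], s=s, rng=rng, dt=dt
        )

    out = usable.loc[usable.index.repeat(n_sim), CELL_KEYS].reset_index(drop=True)
    out["rt_ms"] = rts * 1000.0
    out["correct"] = upper
    out.attrs["skipped"] = skipped
    out.attrs["n_sim"] = n_sim
    return out


def _stream_stats(rt: np.ndarray) -> tuple[float, float, float]:
    return (
        float(np.percentile(rt, 50)),
        float(np.percentile(rt, 5)),
        float(np.percentile(rt, 95)),
    )


def fit_summary(
    observed: pd.DataFrame, simulated: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Per-cell observed vs predicted medians and 5-95% bands.

    For each design cell and each response stream (correct, error):
    the observed median and percentiles, the predicted (simulated) median
    and percentiles, and whether the observed median falls inside the
    predicted 5-95% band. Streams with no observed responses are flagged
    not assessable. Returns the table and the aggregate coverage over
    assessable correct-response cells.
    """
    sim_groups = dict(tuple(simulated.groupby(CELL_KEYS)))
    rows = []
    for key, obs_cell in observed.groupby(CELL_KEYS):
        if key not in sim_groups:
            continue
        sim_cell = sim_groups[key]
        for stream, is_correct in (("correct", True), ("error", False)):
            obs_rt = obs_cell.loc[obs_cell["correct"] == is_correct, "rt_ms"].to_numpy()
            sim_rt = sim_cell.loc[sim_cell["correct"] == is_correct, "rt_ms"].to_numpy()
            row = dict(zip(CELL_KEYS, key))
            row.update(
                {
                    "stream": stream,
                    "n_observed": obs_rt.size,
                    "n_simulated": sim_rt.size,
                    "assessable": bool(obs_rt.size and sim_rt.size),
                }
            )
            if row["assessable"]:
                om, o5, o95 = _stream_stats(obs_rt)
                pm, p5, p95 = _stream_stats(sim_rt)
                row.update(
                    {
                        "observed_median_ms": om,
                        "observed_p5_ms": o5,
                        "observed_p95_ms": o95,
                        "predicted_median_ms": pm,
                        "predicted_p5_ms": p5,
                        "predicted_p95_ms": p95,
                        "within_band": bool(p5 <= om <= p95),
                    }
                )
            else:
                row.update(
                    {
                        "observed_median_ms": np.nan,
                        "observed_p5_ms": np.nan,
                        "observed_p95_ms": np.nan,
                        "predicted_median_ms": np.nan,
                        "predicted_p5_ms": np.nan,
                        "predicted_p95_ms": np.nan,
                        "within_band": False,
                    }
                )
            rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[(table["stream"] == "correct") & table["assessable"]]
    coverage = float(ok["within_band"].mean()) if len(ok) else np.nan
    return table, coverage


def plot_fit(fit_table: pd.DataFrame, path: str | None = None):
    """Observed (circles) vs predicted (crosses) medians per design cell,
    with bars spanning the observed 5th-95th percentiles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = fit_table[(fit_table["stream"] == "correct") & fit_table["assessable"]]
    agg = sub.groupby(["participant_gender", "expression", "required_response",
                       "face_gender"]).agg(
        observed=("observed_median_ms", "mean"),
        predicted=("predicted_median_ms", "mean"),
        lo=("observed_p5_ms", "mean"),
        hi=("observed_p95_ms", "mean"),
    ).reset_index()
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, gender in zip(axes, ("female", "male")):
        g = agg[agg["participant_gender"] == gender]
        labels = [
            f"{e[:1]}/{r[:2]}/{f[:1]}"
            for e, r, f in zip(g["expression"], g["required_response"],
                               g["face_gender"])
        ]
        x = np.arange(len(g))
        ax.errorbar(
            x, g["observed"], yerr=[g["observed"] - g["lo"], g["hi"] - g["observed"]],
            fmt="o", mfc="none", label="observed",
        )
        ax.plot(x, g["predicted"], "x", label="predicted")
        ax.set_xticks(x, labels, rotation=45, fontsize=7)
        ax.set_title(f"{gender} participants")
    axes[0].set_ylabel("median RT (ms)")
    axes[0].legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
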