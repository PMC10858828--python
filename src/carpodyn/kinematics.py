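"""Angle-binned joint-width profiles, paired deltas and instability flags.

Per-frame measurements are grouped into 5-degree wrist-angle bins whose
centres are multiples of the bin width (a measurement at angle a falls in
the bin whose centre is nearest, i.e. bin c covers [c - w/2, c + w/2)).
Profiles report per-bin mean +- SD over frames plus an "Entire" column
pooled over all valid frames — pooled over frames, not averaged over bin
means.  Intra-individual differences (injured minus the same subject's
contralateral control) are taken bin-wise, and a wrist is flagged
dynamically unstable when any bin's mean SL width reaches the 3 mm
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_BIN_WIDTH_DEG = 5.0
INSTABILITY_THRESHOLD_MM = 3.0


@dataclass
class AngleBinProfile:
    """Per-5-degree-bin width statistics plus the frame-pooled overall."""

    bins: pd.DataFrame            # columns: bin_center_deg, mean_mm, sd_mm, n_frames
    overall_mean_mm: float
    overall_sd_mm: float
    overall_n: int
    value: str = "sl"             # which width this profiles ('sl' | 'lt')
    bin_width_deg: float = DEFAULT_BIN_WIDTH_DEG

    def __post_init__(self):
        if (self.bins["n_frames"] < 0).any():
            raise ValueError("negative bin count")
        if int(self.bins["n_frames"].sum()) != self.overall_n:
            raise ValueError("overall n must equal the sum of per-bin counts")

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return self.bins["bin_center_deg"].to_numpy()

    def is_empty(self) -> bool:
        return len(self.bins) == 0


def assign_bin(angle_deg, bin_width_deg: float = DEFAULT_BIN_WIDTH_DEG):
    """Nearest-multiple-of-width bin centre; ties go to the right bin
    (bin c covers [c - w/2, c + w/2))."""
    a = np.asarray(angle_deg, dtype=float)
    c = np.floor(a / bin_width_deg + 0.5) * bin_width_deg
    return float(c) if np.isscalar(angle_deg) else c


def bin_measurements(measurements, value: str = "sl",
                     bin_width_deg: float = DEFAULT_BIN_WIDTH_DEG) -> AngleBinProfile:
    """Bin valid per-frame measurements into an angle profile.

    ``measurements`` is a list of JointMeasurement or a DataFrame from
    ``measurements_to_frame``; ``value`` selects the SL or LT width.
    Invalid frames are excluded.  SD is NaN (flagged undefined) for bins
    with fewer than two frames.
    """
    if value not in ("sl", "lt"):
        raise ValueError("value must be 'sl' or 'lt'")
    if isinstance(measurements, pd.DataFrame):
        df = measurements.rename(columns={"sl_mm": "sl", "lt_mm": "lt",
                                          "angle_deg": "angle"})
    else:
        df = pd.DataFrame({
            "angle": [m.wrist_angle_deg for m in measurements],
            "sl": [m.sl_width_mm for m in measurements],
            "lt": [m.lt_width_mm for m in measurements],
            "valid": [m.valid for m in measurements],
        })
    df = df[df["valid"] & np.isfinite(df["angle"]) & np.isfinite(df[value])]
    if df.empty:
        return AngleBinProfile(
            bins=pd.DataFrame(columns=["bin_center_deg", "mean_mm", "sd_mm",
                                       "n_frames"]),
            overall_mean_mm=np.nan, overall_sd_mm=np.nan, overall_n=0,
            value=value, bin_width_deg=bin_width_deg)

    centers = assign_bin(df["angle"].to_numpy(), bin_width_deg)
    g = df.assign(bin_center_deg=centers).groupby("bin_center_deg")[value]
    bins = pd.DataFrame({
        "bin_center_deg": g.mean().index.to_numpy(),
        "mean_mm": g.mean().to_numpy(),
        "sd_mm": g.std(ddof=1).to_numpy(),   # NaN when n < 2
        "n_frames": g.count().to_numpy(),
    }).reset_index(drop=True)
    vals = df[value].to_numpy()
    return AngleBinProfile(bins=bins, overall_mean_mm=float(vals.mean()),
                           overall_sd_mm=float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                           overall_n=len(vals), value=value,
                           bin_width_deg=bin_width_deg)


@dataclass
class PairedDelta:
    """Bin-wise injured-minus-control width differences."""

    bins: pd.DataFrame            # bin_center_deg, delta_mm, sd_mm, n_injured, n_control
    overall_delta_mm: float
    value: str = "sl"


def paired_delta(injured: AngleBinProfile, control: AngleBinProfile) -> PairedDelta:
    """Intra-individual difference profile on the bins populated in both
    profiles; SD propagated as the root sum of squares."""
    if injured.is_empty() or control.is_empty():
        raise ValueError("both profiles must be non-empty")
    m = injured.bins.merge(control.bins, on="bin_center_deg",
                           suffixes=("_inj", "_ctl"))
    if m.empty:
        raise ValueError("profiles share no populated angle bins")
    bins = pd.DataFrame({
        "bin_center_deg": m["bin_center_deg"],
        "delta_mm": m["mean_mm_inj"] - m["mean_mm_ctl"],
        "sd_mm": np.sqrt(m["sd_mm_inj"].fillna(0.0) ** 2
                         + m["sd_mm_ctl"].fillna(0.0) ** 2),
        "n_injured": m["n_frames_inj"],
        "n_control": m["n_frames_ctl"],
    })
    return PairedDelta(bins=bins,
                       overall_delta_mm=float(injured.overall_mean_mm
                                              - control.overall_mean_mm),
                       value=injured.value)


def flag_instability(profile: AngleBinProfile,
                     threshold_mm: float = INSTABILITY_THRESHOLD_MM):
    """Dynamic-instability flag: true iff any bin mean is >= threshold
    (the literature criterion of SL widths of 3 mm and above).

    Returns ``(flag, offending_bin_centers)``.
    """
    if profile.is_empty():
        raise ValueError("cannot flag an empty profile")
    hit = profile.bins["mean_mm"] >= threshold_mm
    offending = profile.bins.loc[hit, "bin_center_deg"].tolist()
    return bool(hit.any()), offending


def profile_table(profiles: dict[str, AngleBinProfile],
                  fmt: str = "{:.2f}±{:.2f}") -> pd.DataFrame:
    """Group-by-wrist-position table: rows = groups, columns = 'Entire'
    followed by the populated bin centres (mean +- SD strings)."""
    all_bins = sorted({c for p in profiles.values() for c in p.bin_centers_deg})
    cols = ["Entire"] + [f"{c:+.0f}".replace("+-", "-") for c in all_bins]
    rows = {}
    for name, p in profiles.items():
        row = {"Entire": fmt.format(p.overall_mean_mm, p.overall_sd_mm)}
        by_c = p.bins.set_index("bin_center_deg")
        for c in all_bins:
            key = f"{c:+.0f}".replace("+-", "-")
            if c in by_c.index:
                sd = by_c.loc[c, "sd_mm"]
                row[key] = fmt.format(by_c.loc[c, "mean_mm"],
                                      sd if np.isfinite(sd) else float("nan"))
            else:
                row[key] = ""
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")[cols]


def plot_delta(deltas: dict[str, PairedDelta], path=None, title=""):
    """Delta-versus-wrist-position plot (one line per group) to PNG/SVG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for name, d in deltas.items():
        ax.errorbar(d.bins["bin_center_deg"], d.bins["delta_mm"],
                    yerr=d.bins["sd_mm"], marker="o", capsize=3, label=name)
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.set_xlabel("wrist angle [deg, ulnar +]")
    ax.set_ylabel("Δ joint width [mm]")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
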