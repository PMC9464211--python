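"""Plot-ready tidy CSV export of the scenario battery.

One file per figure panel, stable column names, units in ``#`` header
comments: Kr vs time and refilling rate vs time for the LpS set (discarded
and infused priming), the duration set, the Starling-force decomposition,
blood volume and the LpS profiles for the ramp scenarios, and relative
blood volume for the ultrafiltration variants.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .kr import kr_curve, starling_decomposition
from .simulator import Trajectory


def _write(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def _kr_panel(trajs: dict[str, Trajectory], names: list[str],
              column: str) -> pd.DataFrame:
    base = kr_curve(trajs[names[0]])
    out = {"t": base.times}
    for name in names:
        kc = kr_curve(trajs[name])
        out[f"{column}_{name}"] = np.interp(base.times, kc.times, kc.kr) \
            if column == "kr" else np.interp(base.times, kc.times,
                                             kc.refilling_rate)
    return pd.DataFrame(out)


def export_figure_data(trajs: dict[str, Trajectory], out_dir: str | Path) -> list[Path]:
    """Write the per-panel CSVs; returns the created paths.

    Requires the full scenario battery (see
    :func:`refillsim.simulator.scenario_protocols`).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    panels: list[tuple[str, list[str], str, str]] = [
        ("fig2a_kr_by_lps", ["lps4", "basal", "lps8"], "kr",
         "Kr vs time, constant LpS, priming discarded [mL/min/mmHg vs min]"),
        ("fig2b_refilling_by_lps", ["lps4", "basal", "lps8"], "refilling",
         "vascular refilling rate vs time, constant LpS [mL/min vs min]"),
        ("fig4a_kr_by_lps_infused", ["infused_lps4", "infused_basal",
                                     "infused_lps8"], "kr",
         "Kr vs time, constant LpS, priming infused [mL/min/mmHg vs min]"),
        ("fig6a_kr_ramps", ["basal", "lps_ramp_down", "lps_ramp_up"], "kr",
         "Kr vs time, constant vs ramped LpS [mL/min/mmHg vs min]"),
    ]
    for stem, names, col, title in panels:
        df = _kr_panel(trajs, names, "kr" if col == "kr" else "refilling")
        path = out / f"{stem}.csv"
        _write(df, path, [title])
        written.append(path)

    # duration panel on each scenario's own grid (different lengths)
    for stem, names, title in [
            ("fig3a_kr_by_duration", ["dur180", "basal", "dur300"],
             "Kr vs time, 3/4/5 h sessions at 3 L total UF [mL/min/mmHg vs min]")]:
        frames = []
        for name in names:
            kc = kr_curve(trajs[name])
            frames.append(pd.DataFrame(dict(t=kc.times, scenario=name,
                                            kr=kc.kr)))
        path = out / f"{stem}.csv"
        _write(pd.concat(frames, ignore_index=True), path, [title])
        written.append(path)

    # Starling decomposition of the basal session
    dec = starling_decomposition(trajs["basal"]).to_frame()
    path = out / "fig5_starling_forces.csv"
    _write(dec, path,
           ["intradialytic Starling-force changes vs t=0, basal session",
            "sign convention: positive favors transcapillary absorption [mmHg]",
            "lymph_equivalent = change of Q_L/LpS [mmHg], reported separately"])
    written.append(path)

    # blood volume + LpS profiles for the ramp set
    base = trajs["basal"]
    df = pd.DataFrame({"t": base.times})
    for name in ["basal", "lps_ramp_down", "lps_ramp_up"]:
        df[f"blood_volume_{name}"] = trajs[name]["v_blood"]
        df[f"lps_{name}"] = trajs[name]["lps"]
    path = out / "fig6cd_blood_volume_lps_profiles.csv"
    _write(df, path, ["blood volume [mL] and LpS profile [mL/min/mmHg] vs "
                      "time [min], constant vs ramped LpS"])
    written.append(path)

    # relative blood volume for the ultrafiltration variants
    df = pd.DataFrame({"t": base.times})
    for name in ["uf10", "basal", "uf15"]:
        df[f"rbv_{name}"] = trajs[name]["rbv"]
    path = out / "figS1_rbv_by_uf.csv"
    _write(df, path, ["relative blood volume [% of t=0] vs time [min] for "
                      "UF 10/12.5/15 mL/min"])
    written.append(path)
    return written
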