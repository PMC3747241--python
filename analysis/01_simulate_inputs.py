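#!/usr/bin/env python
"""Generate the seeded synthetic field campaign: monthly water samples,
hourly multi-station meteorology and the scene/region geometry.

Writes the sample table, the daily regional meteorology and the
per-scene region water areas under results/, and prints what the
campaign looks like.  Everything downstream (02–05) regenerates the same
world from the same seed, so these files are for inspection, not
hand-off.
"""

import argparse
import warnings
from pathlib import Path

from wetlandco2 import synthetic as syn
from wetlandco2 import upscaling as up


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=str, default="results")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    cfg = syn.SyntheticConfig(seed=args.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        samples, truths = syn.generate_sites(cfg)
        hourly, _ = syn.generate_meteorology(cfg)
        daily = syn.daily_meteo_from_hourly(hourly)
        bundle = syn.generate_scenes(cfg)

    samples.to_csv(out / "samples.csv", index=False)
    daily.to_csv(out / "meteo_daily.csv")

    n_per_site = samples.groupby("site_id").size()
    print(f"{len(samples)} monthly samples at {len(n_per_site)} sites "
          f"(n = {n_per_site.min()}–{n_per_site.max()} per site)")
    print(f"alkalinity {samples.alk_umol_l.min():.0f}–"
          f"{samples.alk_umol_l.max():.0f} umol/L, "
          f"pH {samples.ph_nbs.min():.2f}–{samples.ph_nbs.max():.2f}, "
          f"salinity {samples.salinity.min():.1f}–{samples.salinity.max():.1f}")
    print(f"daily u10 {daily.u10_m_s.min():.1f}–{daily.u10_m_s.max():.1f} m/s "
          f"(median {daily.u10_m_s.median():.2f}); atmospheric pCO2 "
          f"{daily.pco2_atm_uatm.min():.0f}–{daily.pco2_atm_uatm.max():.0f} uatm")

    ref = bundle.scenes[bundle.reference_index]
    rows = []
    for sc in bundle.scenes:
        norm = (sc if sc is ref
                else up.normalize_scene(sc, ref, bundle.pif_pixels))
        mask = up.classify_water(norm)
        for rid, rt in bundle.regions.items():
            rows.append({"date": sc.date.date(), "region_id": rid,
                         "area_km2": up.region_water_area(
                             mask, rt.polygon, sc.pixel_size_m, sc.origin)})
    import pandas as pd
    areas = pd.DataFrame(rows)
    areas.to_csv(out / "region_areas.csv", index=False)
    span = areas.groupby("region_id")["area_km2"].agg(["min", "max"])
    print(f"{len(bundle.scenes)} scenes; water extent per region (km2):")
    print(span.round(3).to_string())


if __name__ == "__main__":
    main()
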