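"""Simulate the synthetic latrine survey that the rest of the analysis uses.

Generates the dendritic network, places latrines, draws the otter
population and its detections, and writes the field bundle (network
GeoJSON, detector CSV, true detection history, sample table) under
results/survey/.
"""

from common import CFG, RESULTS, SEED

from linscr import io as lio
from linscr.simulate import simulate_survey


def main() -> None:
    out = RESULTS / "survey"
    out.mkdir(exist_ok=True)
    data = simulate_survey(CFG, SEED)

    lio.write_network_geojson(data.net, out / "network.geojson")
    lio.write_detectors_csv(data.detectors, data.net, out / "detectors.csv")
    lio.write_history_csv(data.true_history, data.detectors,
                          out / "true_history.csv", out / "true_sexes.csv")
    data.samples.to_csv(out / "samples.csv", index=False)

    n_scats = data.samples["scat_id"].nunique()
    print(f"network: {data.net.n_edges} edges, "
          f"{data.net.total_length / 1000:.1f} km, "
          f"{data.detectors.n_detectors} latrines, "
          f"{data.true_history.n_occasions} occasions")
    print(f"population: {data.true_history.n_individuals} otters simulated "
          f"({data.true_sexes.count('male')} M), "
          f"{data.observed_history.n_individuals} left >=1 scat")
    print(f"field samples: {len(data.samples)} from {n_scats} scats "
          f"({len(data.samples) / n_scats:.2f} samples/scat)")


if __name__ == "__main__":
    main()
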