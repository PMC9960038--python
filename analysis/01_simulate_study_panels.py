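"""Generate the synthetic study panels used throughout the analysis.

Writes three scenarios under results/panels/: a unit-test-scale panel, a
study-scale panel (100 areas x 15 years, ACS-style covariates, ~73%
urban areas holding almost all person-years), and a sparse-rural panel
dominated by zero counts.  Each scenario gets the panel CSV, the
adjacency edge list, and the generating truth as JSON.
"""

from pathlib import Path

from areacast.graph import write_adjacency
from areacast.model import write_panel_csv
from areacast.simulate import FIXTURE_NAMES, make_fixture

OUT = Path(__file__).resolve().parent.parent / "results" / "panels"
SEED = 20230210


def main() -> None:
    for name in FIXTURE_NAMES:
        data, graph, truth = make_fixture(name, SEED)
        outdir = OUT / name
        outdir.mkdir(parents=True, exist_ok=True)
        write_panel_csv(data, outdir / "panel.csv")
        write_adjacency(graph, outdir / "adjacency.txt")
        (outdir / "truth.json").write_text(truth.to_json())
        urban_deaths = data.deaths[data.urban].sum()
        print(
            f"{name:>12}: {data.n_areas} areas x {data.n_years} years, "
            f"{int(data.deaths.sum())} deaths "
            f"({urban_deaths / max(data.deaths.sum(), 1):.0%} urban), "
            f"{int(data.urban.sum())} urban areas"
        )


if __name__ == "__main__":
    main()
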