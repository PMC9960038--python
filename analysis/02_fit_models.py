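"""Fit all three model variants to the study-scale panel.

Reads results/panels/standard, fits the temporal-pooling model (1), the
exchangeable-interaction model (2), and the CAR-interaction model (3),
each with and without covariates, and writes posterior summaries and
convergence diagnostics under results/fits/.
"""

from pathlib import Path

from areacast.graph import read_adjacency
from areacast.mcmc import McmcConfig, diagnostics, fit, summarize
from areacast.model import ModelSpec, read_panel_csv, standardize_covariates

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 7


def main() -> None:
    data = read_panel_csv(ROOT / "panels" / "standard" / "panel.csv")
    graph = read_adjacency(ROOT / "panels" / "standard" / "adjacency.txt",
                           area_ids=data.area_ids)
    data = standardize_covariates(data)
    outdir = ROOT / "fits"
    outdir.mkdir(parents=True, exist_ok=True)
    for variant in ("model1", "model2", "model3"):
        for with_cov in (False, True):
            spec = ModelSpec(variant=variant, include_covariates=with_cov)
            cfg = McmcConfig(n_iterations=3000, n_burnin=1000, thin=4,
                             seed=SEED + hash(spec.label) % 1000)
            draws = fit(spec, data, graph, cfg)
            s = summarize(draws)
            s.to_csv(outdir / f"{spec.label}_summary.csv")
            diagnostics(draws).to_csv(outdir / f"{spec.label}_diagnostics.csv")
            print(f"{spec.label:>12}: alpha median {s.loc['alpha', 'median']:.3f}, "
                  f"acceptance {draws.acceptance}")


if __name__ == "__main__":
    main()
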