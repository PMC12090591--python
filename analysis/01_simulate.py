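"""Simulate the study-scale dataset every later analysis step consumes.

Draws n = 367 patients' ordinal symptom scores (19 symptoms, 0-10 scale)
from the study-scale ground-truth network with marginals calibrated to the
published prevalence/severity table, and writes the scores plus the ground
truth to results/data/.
"""

from pathlib import Path

from symptomnet import generate_dataset, study_true_network, table2_marginals

SEED = 2024
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth = study_true_network()
    marginals = table2_marginals(warn=False)
    data = generate_dataset(truth, marginals, n=367, seed=SEED)
    data.to_csv(OUT / "scores.csv")
    truth.to_json(OUT / "true_network.json", seed=SEED)
    print(f"wrote {data.n} patients x {data.p} symptoms -> {OUT / 'scores.csv'}")
    print(f"ground truth ({int((truth.partials != 0).sum() / 2)} edges) -> true_network.json")


if __name__ == "__main__":
    main()
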