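"""Run the full protocol on the public ACP240 / ACP740 benchmark datasets.

Optional: requires network access (or pre-downloaded files) and several
minutes of compute.  Downloads the datasets from the ACP-DL repository,
runs five-fold cross-validation of baseline / TDA / ASSF with the default
hyperparameters, and prints the resulting metric tables.  Nothing is
asserted; this script exists for manual comparison only.

    python scripts/reproduce_acp.py --dataset acp240 [--data-dir scratch/]
"""

from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

import acps_assf as aa

BASE = "https://raw.githubusercontent.com/haichengyi/ACP-DL/master"
FILES = {
    "acp240": "ACP240.txt",
    "acp740": "ACP740.txt",
}
BATCH_SIZES = {"acp240": 32, "acp740": 64}


def fetch(dataset: str, data_dir: Path) -> Path:
    data_dir.mkdir(parents=True, exist_ok=True)
    path = data_dir / FILES[dataset]
    if not path.exists():
        url = f"{BASE}/{FILES[dataset]}"
        print(f"downloading {url}")
        urllib.request.urlretrieve(url, path)
    return path


def load(path: Path) -> aa.LabeledDataset:
    """ACP-DL distributes FASTA with a trailing |label token on each header."""
    return aa.read_labeled_fasta(path, label_scheme="header_suffix")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dataset", choices=sorted(FILES), default="acp240")
    parser.add_argument("--data-dir", type=Path, default=Path("scratch"))
    parser.add_argument("--omega", type=float, default=0.006)
    parser.add_argument("--ratio", type=int, default=2)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    data = load(fetch(args.dataset, args.data_dir))
    n_pos = int(data.labels.sum())
    print(f"{args.dataset}: {len(data)} peptides ({n_pos} ACP / {len(data) - n_pos} non-ACP)")

    cfg = aa.AssfConfig(
        train=aa.TrainConfig(batch_size=BATCH_SIZES[args.dataset], seed=args.seed),
        model=aa.ModelConfig(seed=args.seed),
    )
    spec = aa.PerturbationSpec(omega=args.omega, ratio=args.ratio, seed=args.seed)
    for method in ("baseline", "tda", "assf"):
        result = aa.cross_validate(
            data, method, cfg, spec=spec, folds=5, seed=args.seed
        )
        mm = result.mean_metrics
        print(
            f"{method:>8}: acc={100 * mm['accuracy']:.2f}  "
            f"sp={100 * mm['specificity']:.2f}  f1={100 * mm['f1']:.2f}  "
            f"mcc={100 * mm['mcc']:.2f}"
        )


if __name__ == "__main__":
    main()
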