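"""Train the SKiNET classifier and extract the SOMDI discriminant bands.

Loads the preprocessed spectra, vector-normalises them, holds out a
stratified 30% test split, trains the 10x10 hexagonal self-organizing map
with co-trained class-label vectors, and writes:

  results/som_map.csv        per-neuron coordinates, majority class, label weights
  results/map_positions.csv  best-matching-unit coordinates per sample
  results/somdi.csv          per-class discriminant spectra
  results/classification.csv held-out predictions

The discriminant should concentrate on the injury-sensitive bands near
1003, 1266, 1337, 1447 and 1660 cm^-1.

Run from the repository root:  python analysis/03_train_som.py
"""

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from neuroraman import TrainConfig, classify, compute_somdi, map_positions, train_som
from neuroraman.io import read_labels, read_spectrum
from neuroraman.pipeline import top_somdi_bands

IN = Path("scratch/preprocessed")
SEED = 20260929


def main():
    labels_df = read_labels("scratch/cohort/labels.csv")
    spectra, labels, ids = [], [], []
    for _, row in labels_df.iterrows():
        spec = read_spectrum(IN / f"{row['sample_id']}.csv")
        spectra.append(spec)
        labels.append(row["class"])
        ids.append(row["sample_id"])
    axis = spectra[0].axis
    X = np.vstack([s.intensity for s in spectra])
    X /= np.linalg.norm(X, axis=1, keepdims=True)

    idx = np.arange(len(labels))
    tr, te = train_test_split(idx, test_size=0.3, stratify=labels,
                              random_state=SEED % (2**31))
    model = train_som(X[tr], [labels[i] for i in tr],
                      TrainConfig(seed=SEED % (2**31)), axis=axis)

    pred = [classify(model, X[i]) for i in te]
    acc = np.mean([p[0] == labels[i] for p, i in zip(pred, te)])
    pd.DataFrame({
        "sample_id": [ids[i] for i in te],
        "true_class": [labels[i] for i in te],
        "predicted": [p[0] for p in pred],
        "confidence": [p[1] for p in pred],
    }).to_csv("results/classification.csv", index=False, float_format="%.4g")

    positions = map_positions(model, X)
    pd.DataFrame({"sample_id": ids, "class": labels,
                  "q": [p[0] for p in positions],
                  "r": [p[1] for p in positions]}
                 ).to_csv("results/map_positions.csv", index=False)

    lw = model.label_weights
    map_df = pd.DataFrame({
        "q": model.coords[:, 0], "r": model.coords[:, 1],
        "majority_class": [model.class_names[int(k)] for k in lw.argmax(axis=1)],
    })
    for c, name in enumerate(model.class_names):
        map_df[f"w_{name}"] = lw[:, c]
    map_df.to_csv("results/som_map.csv", index=False, float_format="%.6g")

    somdi = compute_somdi(model)
    somdi_df = pd.DataFrame({"wavenumber_cm-1": somdi.axis})
    for name in model.class_names:
        somdi_df[name] = somdi.vector(name)
    somdi_df.to_csv("results/somdi.csv", index=False, float_format="%.6g")

    print(f"trained {model.grid_width}x{model.grid_height} SOM "
          f"on {len(tr)} spectra; held-out accuracy {acc:.2f} on {len(te)}")
    for name in model.class_names:
        bands = top_somdi_bands(somdi, name)
        print(f"  top SOMDI bands, {name}: "
              + ", ".join(f"{b:.0f}" for b in bands) + " cm-1")


if __name__ == "__main__":
    main()
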