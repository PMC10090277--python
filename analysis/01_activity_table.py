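"""Load the 22-compound nitrogen-mustard activity table and transform it.

Writes results/activity_table.csv with IC50 (µM), the transformed activity
−log10(IC50)+6, and the train/test split, and prints the range of the series.
"""

from pathlib import Path

from nmqsar import chem_data

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ds = chem_data.load_fixture()
    df = ds.to_frame()
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "activity_table.csv", index=False)

    most = df.loc[df.ic50_uM.idxmin()]
    least = df.loc[df.ic50_uM.idxmax()]
    print(f"{len(df)} compounds ({ds.n_train} train / {ds.n_test} test)")
    print(f"most potent:  {most.id}  IC50 {most.ic50_uM} µM  activity {most.activity:.4f}")
    print(f"least potent: {least.id}  IC50 {least.ic50_uM} µM  activity {least.activity:.4f}")
    print(f"wrote {OUT / 'activity_table.csv'}")


if __name__ == "__main__":
    main()
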