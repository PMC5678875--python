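"""Apply the inclusion filters and sample one daily profile per child.

A day is kept when it has at least 600 worn minutes between 07:00 and
22:00 and all 660 one-minute epochs of the 08:30-19:30 common window;
one eligible day per child is then drawn at random so profiles are
independent.  Writes the QC summary to results/ and the sampled
profile matrix to scratch/analysis/.
"""

import pandas as pd

from fanova_activity.epochs import parse_epoch_csv, qc_days, sample_one_profile_per_child
from fanova_activity.timegrid import MINUTE_GRID
from paths import RESULTS, SCRATCH, SEED_SAMPLING


def main() -> None:
    series = parse_epoch_csv(SCRATCH / "data" / "epochs.csv")
    profiles, report = qc_days(series)
    summary = (
        report.assign(outcome=report["reason"].replace("", "eligible"))
        .groupby("outcome").size().rename("days").reset_index()
    )
    summary.to_csv(RESULTS / "qc_summary.csv", index=False)
    print(summary.to_string(index=False))
    print(f"{report['eligible'].mean():.1%} of {len(report)} child-days eligible")

    covariates = pd.read_csv(SCRATCH / "data" / "covariates.csv", dtype={"child_id": str})
    dataset = sample_one_profile_per_child(profiles, covariates, SEED_SAMPLING)
    mat = pd.DataFrame(dataset.profiles, columns=[str(int(t)) for t in MINUTE_GRID])
    mat.insert(0, "child_id", dataset.child_ids)
    mat.to_csv(SCRATCH / "profiles.csv", index=False)
    print(f"sampled one profile for each of {dataset.n} children -> {SCRATCH / 'profiles.csv'}")


if __name__ == "__main__":
    main()
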