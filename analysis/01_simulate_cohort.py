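"""Generate the study cohort: a labelled two-sector synthetic panel.

Emits the record and truth-table CSVs under scratch/ (they are bulky)
and a small per-sector summary under results/.
"""
from pathlib import Path

from raiaudit.records import write_frame

from cohort_setup import DICTIONARY, injected_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    config, frame, truth = injected_cohort()
    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    write_frame(frame, scratch / "cohort.csv", DICTIONARY)
    truth.to_csv(scratch / "truth.csv", index=False)

    summary = frame.groupby("sector").agg(
        records=("person_id", "size"),
        persons=("person_id", "nunique"),
        facilities=("facility_id", "nunique"),
    )
    summary["admission_share"] = frame.groupby("sector")["assessment_type"].apply(
        lambda s: round((s == "admission").mean(), 3))
    summary["assessments_per_person"] = (summary["records"] / summary["persons"]).round(2)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    summary.to_csv(results / "cohort_summary.csv")
    print("Cohort generated:")
    print(summary.to_string())
    injected = truth.filter(like="injected_").sum().sum()
    print(f"\n{injected} labelled errors injected across "
          f"{truth.filter(like='injected_').shape[1]} error types.")


if __name__ == "__main__":
    main()
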