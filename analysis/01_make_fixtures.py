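"""Materialize the 14-case synthetic input bundles.

Writes metadata.tsv, cytobands.json and per-case Arriba-style fusion TSVs
plus per-exon coverage tables under results/fixtures/.  These are the
deterministic inputs every downstream step consumes; Case 9 deliberately
has a header-only fusion file (its event is only visible in coverage).
"""

from pathlib import Path

from fusionframe.synthetic_data import write_case_fixtures

OUT = Path(__file__).resolve().parents[1] / "results" / "fixtures"


def main() -> None:
    write_case_fixtures(OUT)
    n_cases = len(list(OUT.glob("case_*")))
    print(f"wrote {n_cases} case bundles to {OUT}")
    empty = [
        d.name for d in sorted(OUT.glob("case_*"))
        if len((d / "fusions.tsv").read_text().strip().splitlines()) == 1
    ]
    print(f"caller-negative cases (header-only fusion file): {empty}")


if __name__ == "__main__":
    main()
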