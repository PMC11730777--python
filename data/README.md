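# Study data

The reproduction test in `tests/test_acceptance.py` expects the deposited
individual-level rotifer life-history records
(https://zenodo.org/doi/10.5281/zenodo.11125048) converted to the
package's canonical long-format CSV and saved here as
`study_life_histories.csv`, with columns

    individual_id, treatment, maternal_age, age_day, status, offspring

where `treatment` is `AL` or `LF`, `status` is `alive`/`dead`/`censored`,
and each individual's rows run daily from `age_day = 1` to its terminal
record (see `matage.data_io` for the exact invariants, and
`matage.read_life_histories(path, schema=...)` for column-name mapping).
The data are not redistributed with the package; without this file the
reproduction test reports the data as unavailable.
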