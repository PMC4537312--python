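{
  "description": "Published stratified prevalence of four extrapyramidal side effects in a cohort of 12,879 patients with serious mental illness (2007-2013) from a de-identified psychiatric case register, with published Pearson chi-square heterogeneity statistics (no continuity correction). Percent prevalences are as printed (two decimals); per-stratum counts were not printed and are reconstructed by round-half-up(prevalence x cohort).",
  "total_cohort": 12879,
  "ade_ids": ["dystonia", "akathisia", "parkinsonism", "tardive dyskinesia"],
  "total_positive": {
    "dystonia": 390,
    "akathisia": 750,
    "parkinsonism": 440,
    "tardive dyskinesia": 324
  },
  "partitions": {
    "age": {
      "strata": [
        {"label": "Under 21", "cohort_size": 318, "prevalence_percent": {"dystonia": 5.97, "akathisia": 8.18, "parkinsonism": 3.46, "tardive dyskinesia": 0.63}},
        {"label": "21 to 30", "cohort_size": 2106, "prevalence_percent": {"dystonia": 4.51, "akathisia": 6.03, "parkinsonism": 2.71, "tardive dyskinesia": 1.47}},
        {"label": "31 to 40", "cohort_size": 3018, "prevalence_percent": {"dystonia": 3.61, "akathisia": 5.40, "parkinsonism": 2.78, "tardive dyskinesia": 1.46}},
        {"label": "41 to 50", "cohort_size": 3249, "prevalence_percent": {"dystonia": 2.65, "akathisia": 6.25, "parkinsonism": 2.22, "tardive dyskinesia": 2.28}},
        {"label": "51 to 60", "cohort_size": 2119, "prevalence_percent": {"dystonia": 2.27, "akathisia": 5.85, "parkinsonism": 3.21, "tardive dyskinesia": 2.41}},
        {"label": "61 to 70", "cohort_size": 1129, "prevalence_percent": {"dystonia": 1.86, "akathisia": 5.93, "parkinsonism": 6.20, "tardive dyskinesia": 5.23}},
        {"label": "71 to 80", "cohort_size": 677, "prevalence_percent": {"dystonia": 1.33, "akathisia": 4.73, "parkinsonism": 9.31, "tardive dyskinesia": 7.39}},
        {"label": "Above 80", "cohort_size": 263, "prevalence_percent": {"dystonia": 1.14, "akathisia": 3.04, "parkinsonism": 5.70, "tardive dyskinesia": 4.94}}
      ],
      "published_chi_square": {"dystonia": 49.568, "akathisia": 10.648, "parkinsonism": 123.193},
      "note": "The published tardive-dyskinesia age statistic duplicates the akathisia value and does not recompute; it is omitted here."
    },
    "gender": {
      "strata": [
        {"label": "Male", "cohort_size": 6969, "prevalence_percent": {"dystonia": 3.49, "akathisia": 6.50, "parkinsonism": 3.26, "tardive dyskinesia": 2.55}},
        {"label": "Female", "cohort_size": 5910, "prevalence_percent": {"dystonia": 2.49, "akathisia": 5.03, "parkinsonism": 3.60, "tardive dyskinesia": 2.47}}
      ],
      "published_chi_square": {"dystonia": 10.881, "akathisia": 12.684, "parkinsonism": 1.165, "tardive dyskinesia": 0.092}
    },
    "ethnicity": {
      "strata": [
        {"label": "White", "cohort_size": 5788, "prevalence_percent": {"dystonia": 2.32, "akathisia": 6.10, "parkinsonism": 3.27, "tardive dyskinesia": 2.16}},
        {"label": "Black", "cohort_size": 4682, "prevalence_percent": {"dystonia": 4.44, "akathisia": 5.55, "parkinsonism": 3.55, "tardive dyskinesia": 3.25}},
        {"label": "Asians", "cohort_size": 861, "prevalence_percent": {"dystonia": 2.32, "akathisia": 8.13, "parkinsonism": 6.04, "tardive dyskinesia": 3.14}},
        {"label": "Other", "cohort_size": 1548, "prevalence_percent": {"dystonia": 1.81, "akathisia": 4.33, "parkinsonism": 2.13, "tardive dyskinesia": 1.29}}
      ],
      "published_chi_square": {"dystonia": 51.214, "akathisia": 16.088, "parkinsonism": 26.332, "tardive dyskinesia": 23.990}
    },
    "diagnosis": {
      "strata": [
        {"label": "Schizophreniform", "cohort_size": 8411, "prevalence_percent": {"dystonia": 3.11, "akathisia": 5.91, "parkinsonism": 3.40, "tardive dyskinesia": 2.87}},
        {"label": "Bipolar", "cohort_size": 3208, "prevalence_percent": {"dystonia": 2.03, "akathisia": 3.99, "parkinsonism": 2.77, "tardive dyskinesia": 1.00}},
        {"label": "Schizoaffective", "cohort_size": 1260, "prevalence_percent": {"dystonia": 5.00, "akathisia": 9.92, "parkinsonism": 5.16, "tardive dyskinesia": 4.05}}
      ],
      "published_chi_square": {"dystonia": 27.867, "akathisia": 58.342, "parkinsonism": 15.607, "tardive dyskinesia": 46.399}
    }
  }
}
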