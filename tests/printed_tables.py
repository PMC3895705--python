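"""Published descriptive-table inputs used as regression-test oracles.

Raw category counts from the study's two descriptive tables, with the
one-decimal percentages they print.  Each variable uses its own
complete-case denominator; the sex row additionally prints an explicit
"No response" category.  The "decision to escape home" row is omitted:
its printed percentages (6.2 / 93.8) are inconsistent with any common
denominator for the printed counts (85 / 1370).
"""

# variable -> (counts per category, expected percents, include_missing_row,
#              missing count)
TABLE1 = {
    "sex": ({"Boys": 535, "Girls": 919}, (36.1, 62.1, 1.8), True, 27),
    "marital_status": ({"Not married but engaged": 167, "Single": 1273},
                       (11.6, 88.4), False, 0),
    "age_group": ({"18-21": 867, "22-24": 571}, (60.3, 39.7), False, 0),
    "residence": ({"Urban": 1272, "Rural": 118}, (91.5, 8.5), False, 0),
    "life_skill_course": ({"Pass": 525, "Not pass": 929}, (36.1, 63.9), False, 0),
    "family_planning_course": ({"Pass": 477, "Not pass": 977}, (32.8, 67.2),
                               False, 0),
    "religious_attendance": ({"Never": 99, "Seldom": 379, "Sometimes": 619,
                              "Often": 346}, (6.9, 26.3, 42.9, 24.0), False, 0),
    "violent_media": ({"No": 288, "Yes": 1166}, (19.8, 80.2), False, 0),
}

# media category -> (girls count, boys count); girls total 919, boys 535.
TABLE2_COUNTS = {
    "Book": (52, 21),
    "Film": (290, 160),
    "Picture": (78, 31),
    "Satellite": (94, 51),
    "Other": (5, 6),
    "Combination": (197, 181),
    "No use": (203, 85),
}

TABLE2_PERCENTS = {
    "Book": (5.7, 3.9, 5.0),           # girls, boys, total
    "Film": (31.6, 29.9, 30.9),
    "Picture": (8.5, 5.8, 7.5),
    "Satellite": (10.2, 9.5, 10.0),
    "Other": (0.5, 1.1, 0.8),
    "Combination": (21.4, 33.8, 26.0),
    "No use": (22.1, 15.9, 19.8),
}
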