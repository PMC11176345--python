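{
  "schema_version": "1",
  "rates": [
    {"role": "SP", "rate_eur_per_min": "0.5498", "tariff_percent_per_min": "0.001"},
    {"role": "PH", "rate_eur_per_min": "0.8027", "tariff_percent_per_min": "0.001"}
  ],
  "items": [
    {
      "item_id": "doc-screening-baseline",
      "label": "Documentation screening and baseline",
      "data_points": "400",
      "sp_minutes": "183", "sp_cost_eur": "101.00",
      "ph_minutes": "18.3", "ph_cost_eur": "15.00",
      "ms_minutes": "", "ms_cost_eur": "",
      "material_cost_eur": "0.00",
      "overhead_rate": "0",
      "printed_total_eur": "115.00"
    },
    {
      "item_id": "doc-ward",
      "label": "Documentation hospital ward",
      "data_points": "100",
      "sp_minutes": "105", "sp_cost_eur": "58.00",
      "ph_minutes": "10.5", "ph_cost_eur": "8.00",
      "ms_minutes": "", "ms_cost_eur": "",
      "material_cost_eur": "0.00",
      "overhead_rate": "0",
      "printed_total_eur": "66.00"
    },
    {
      "item_id": "doc-icu",
      "label": "Documentation ICU",
      "data_points": "200",
      "sp_minutes": "195", "sp_cost_eur": "107.00",
      "ph_minutes": "19.5", "ph_cost_eur": "16.00",
      "ms_minutes": "", "ms_cost_eur": "",
      "material_cost_eur": "0.00",
      "overhead_rate": "0",
      "printed_total_eur": "123.00"
    },
    {
      "item_id": "clinical-status",
      "label": "Document clinical status",
      "data_points": "",
      "sp_minutes": "10", "sp_cost_eur": "5.50",
      "ph_minutes": "", "ph_cost_eur": "",
      "ms_minutes": "", "ms_cost_eur": "",
      "material_cost_eur": "0.00",
      "overhead_rate": "0",
      "printed_total_eur": "5.50"
    },
    {
      "item_id": "ecg",
      "label": "Electrocardiography",
      "data_points": "",
      "sp_minutes": "10", "sp_cost_eur": "5.50",
      "ph_minutes": "", "ph_cost_eur": "",
      "ms_minutes": "10", "ms_cost_eur": "11.17",
      "material_cost_eur": "1.00",
      "overhead_rate": "0",
      "printed_total_eur": "17.67"
    },
    {
      "item_id": "pbmc",
      "label": "PBMCs from 9 ml EDTA",
      "data_points": "",
      "sp_minutes": "120", "sp_cost_eur": "65.97",
      "ph_minutes": "", "ph_cost_eur": "",
      "ms_minutes": "", "ms_cost_eur": "",
      "material_cost_eur": "5.00",
      "overhead_rate": "0",
      "printed_total_eur": "70.97"
    },
    {
      "item_id": "spirometry",
      "label": "Spirometry with plethysmograph and diffusion measurement",
      "data_points": "",
      "sp_minutes": "90", "sp_cost_eur": "49.48",
      "ph_minutes": "60", "ph_cost_eur": "48.16",
      "ms_minutes": "30", "ms_cost_eur": "36.16",
      "material_cost_eur": "70.00",
      "overhead_rate": "0",
      "printed_total_eur": "203.80"
    },
    {
      "item_id": "echocardiogram",
      "label": "Transthoracic echocardiogram",
      "data_points": "",
      "sp_minutes": "15", "sp_cost_eur": "8.25",
      "ph_minutes": "", "ph_cost_eur": "",
      "ms_minutes": "45", "ms_cost_eur": "50.28",
      "material_cost_eur": "25.00",
      "overhead_rate": "0",
      "printed_total_eur": "83.52"
    }
  ],
  "visits": [
    {
      "visit_type_id": "baseline",
      "cohort": null,
      "centre_class": null,
      "items": [
        {"item_id": "doc-screening-baseline", "count": 1},
        {"item_id": "clinical-status", "count": 1},
        {"item_id": "ecg", "count": 1}
      ]
    },
    {
      "visit_type_id": "ward-day",
      "cohort": null,
      "centre_class": null,
      "items": [
        {"item_id": "doc-ward", "count": 1},
        {"item_id": "clinical-status", "count": 1}
      ]
    },
    {
      "visit_type_id": "icu-day",
      "cohort": null,
      "centre_class": null,
      "items": [
        {"item_id": "doc-icu", "count": 1}
      ]
    },
    {
      "visit_type_id": "discharge",
      "cohort": null,
      "centre_class": null,
      "items": [
        {"item_id": "clinical-status", "count": 1},
        {"item_id": "spirometry", "count": 1}
      ]
    },
    {
      "visit_type_id": "fu-3mo",
      "cohort": null,
      "centre_class": null,
      "items": [
        {"item_id": "clinical-status", "count": 1},
        {"item_id": "ecg", "count": 1}
      ]
    },
    {
      "visit_type_id": "fu-12mo",
      "cohort": null,
      "centre_class": null,
      "items": [
        {"item_id": "clinical-status", "count": 1},
        {"item_id": "spirometry", "count": 1}
      ]
    },
    {
      "visit_type_id": "pop-initial-interview",
      "cohort": "POP",
      "centre_class": null,
      "items": [
        {"item_id": "clinical-status", "count": 1}
      ]
    },
    {
      "visit_type_id": "pop-onsite",
      "cohort": "POP",
      "centre_class": null,
      "items": [
        {"item_id": "doc-screening-baseline", "count": 1},
        {"item_id": "ecg", "count": 1},
        {"item_id": "spirometry", "count": 1}
      ]
    }
  ]
}
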