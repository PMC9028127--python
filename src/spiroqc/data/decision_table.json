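{
  "comment": "Acceptability/usability decision table per ATS/ERS 2019. Each criterion names the index it affects and whether a failure voids only acceptability or also usability. window: where on the time axis the offending evidence must fall ('first_second' = overlapping [t0, t0+1s]).",
  "criteria": [
    {
      "id": "bev_limit",
      "description": "Back-extrapolated volume within max(bev_abs, bev_frac x FVC)",
      "fev1": "usability",
      "fvc": "usability",
      "window": "start"
    },
    {
      "id": "fev1_measurable",
      "description": "Recording extends to at least 1 s past time zero",
      "fev1": "usability",
      "fvc": "none",
      "window": "first_second"
    },
    {
      "id": "cough_first_second",
      "description": "No cough in the first second of expiration",
      "fev1": "usability",
      "fvc": "none",
      "window": "first_second"
    },
    {
      "id": "glottic_closure_first_second",
      "description": "No glottic closure in the first second of expiration",
      "fev1": "usability",
      "fvc": "none",
      "window": "first_second"
    },
    {
      "id": "glottic_closure_any",
      "description": "No glottic closure during the expiration",
      "fev1": "none",
      "fvc": "acceptability",
      "window": "any"
    },
    {
      "id": "flutter_first_second",
      "description": "No mouthpiece/device flutter in the first second",
      "fev1": "usability",
      "fvc": "none",
      "window": "first_second"
    },
    {
      "id": "flutter_any",
      "description": "No mouthpiece/device flutter corrupting the volume record",
      "fev1": "none",
      "fvc": "usability",
      "window": "any"
    },
    {
      "id": "extra_breath_first_second",
      "description": "No extra breath in the first second of expiration",
      "fev1": "acceptability",
      "fvc": "none",
      "window": "first_second"
    },
    {
      "id": "extra_breath_any",
      "description": "No extra breath during the maneuver",
      "fev1": "none",
      "fvc": "usability",
      "window": "any"
    },
    {
      "id": "hesitant_start",
      "description": "No hesitant start (excessive back-extrapolated volume)",
      "fev1": "acceptability",
      "fvc": "none",
      "window": "start"
    },
    {
      "id": "variable_flow",
      "description": "Peak flow reached promptly (tPEF within limit)",
      "fev1": "acceptability",
      "fvc": "none",
      "window": "start"
    },
    {
      "id": "eofe",
      "description": "End of forced expiration reached (plateau, long FET, or session FVC repeatability)",
      "fev1": "none",
      "fvc": "acceptability",
      "window": "end"
    },
    {
      "id": "early_termination",
      "description": "Expiration not cut short before an EOFE indicator",
      "fev1": "none",
      "fvc": "acceptability",
      "window": "end"
    }
  ]
}
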