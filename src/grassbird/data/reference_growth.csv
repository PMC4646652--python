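policy,profit_maximizing_producer,small_scale_farmer,conservationist
outreach_marketing,0.0287,0.0353,0.0427
regulatory_enforcement,-0.0569,0.0235,0.0431
public_land_acquisition,-0.0863,0.0308,0.0442
best_management_practices,-0.0715,0.0361,0.0436
ecosystem_services_payments,0.0041,0.0376,0.0427
economic_incentives,-0.0106,0.0370,0.0435
status_quo,-0.0733,0.0292,0.0438
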