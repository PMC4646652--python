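landowner,policy,birds,carbon,water_quality,financial_profit,biodiversity
profit_maximizing_producer,outreach_marketing,0.15,0.21,0.21,0.30,0.12
profit_maximizing_producer,regulatory_enforcement,0.00,0.08,0.08,0.83,0.00
profit_maximizing_producer,public_land_acquisition,0.00,0.00,0.00,1.00,0.00
profit_maximizing_producer,best_management_practices,0.00,0.00,0.00,1.00,0.00
profit_maximizing_producer,ecosystem_services_payments,0.03,0.15,0.15,0.51,0.15
profit_maximizing_producer,economic_incentives,0.03,0.13,0.13,0.67,0.03
profit_maximizing_producer,status_quo,0.00,0.00,0.00,1.00,0.00
small_scale_farmer,outreach_marketing,0.23,0.07,0.10,0.33,0.27
small_scale_farmer,regulatory_enforcement,0.20,0.00,0.10,0.50,0.20
small_scale_farmer,public_land_acquisition,0.20,0.00,0.20,0.40,0.20
small_scale_farmer,best_management_practices,0.23,0.06,0.16,0.32,0.23
small_scale_farmer,ecosystem_services_payments,0.24,0.00,0.17,0.34,0.24
small_scale_farmer,economic_incentives,0.26,0.00,0.15,0.37,0.22
small_scale_farmer,status_quo,0.23,0.00,0.09,0.45,0.23
conservationist,outreach_marketing,0.24,0.17,0.17,0.19,0.24
conservationist,regulatory_enforcement,0.29,0.11,0.11,0.23,0.26
conservationist,public_land_acquisition,0.29,0.12,0.12,0.24,0.24
conservationist,best_management_practices,0.25,0.15,0.18,0.20,0.23
conservationist,ecosystem_services_payments,0.26,0.10,0.18,0.23,0.23
conservationist,economic_incentives,0.27,0.11,0.16,0.24,0.22
conservationist,status_quo,0.30,0.12,0.12,0.24,0.21
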