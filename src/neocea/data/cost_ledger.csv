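component,reported_amount,adjustment_class
funder,981577.62,cpi_all_items
participant,31938.20,cpi_all_items
value_time,417200.00,cpi_physician_services
local_partner,92229.72,ppp_then_cpi
other,67330.43,cpi_medical_commodities
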