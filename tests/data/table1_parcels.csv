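parcel_id,year_built,appraised_value,grade
Property 1,1985,"$156,000",C
Property 2,1971,"$275,000",B
Property 3,1965,"$130,000",C
Property 4,1961,"$70,000",C-
Property 5,1955,"$270,000",B-
Property 6,1951,"$145,000",C--
Property 7,1943,"$60,000",D+
Property 8,1932,"$265,000",A-
Property 9,1927,"$130,000",C++
Property 10,1910,"$50,000",D
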