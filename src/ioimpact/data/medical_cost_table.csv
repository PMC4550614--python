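item,sector,value_billion_yen,is_personnel,is_depreciation,is_goods
personal_expenses,Compensation of employees,12218.4,True,False,False
medicine,Chemical products,4387.2,False,False,True
food_material,Foods,196.4,False,False,True
medical_materials,Miscellaneous manufacturing products,2025.9,False,False,True
utility_costs,"Electricity, gas and heat supply",353.4,False,False,False
land_and_building_rents,Real estate,467.6,False,False,False
equipment_rentals,Business services,2156.5,False,False,False
consignment_laboratory_tests,Business services,1063.2,False,False,False
patient_meal_service,Foods,210.3,False,False,True
linen_and_gown_cleaning,Personal services,70.0,False,False,False
medical_waste_disposal,Water supply and waste management services,48.7,False,False,False
depreciation,Depreciation of fixed capital,1495.9,False,True,False
others,Business services,132.0,False,False,False
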