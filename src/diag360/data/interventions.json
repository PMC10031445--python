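{
  "schema_id": "diag360.catalog",
  "schema_version": 1,
  "interventions": [
    {
      "id": "mindfulness_group",
      "name": "Mindfulness group course",
      "category": "group_based",
      "availability": "within_municipality",
      "targets": ["perceived_stress", "mental_health"],
      "description": "Weekly group sessions teaching mindfulness to prevent stress."
    },
    {
      "id": "walking_club",
      "name": "Neighborhood walking club",
      "category": "group_based",
      "availability": "proximity_to_practice",
      "targets": ["physical_activity", "weight"],
      "description": "Guided group walks starting near the practice."
    },
    {
      "id": "buddy_program",
      "name": "Diabetes buddy program",
      "category": "group_based",
      "availability": "within_municipality",
      "targets": ["loneliness", "family"],
      "description": "Pairs participants with a trained peer for regular contact."
    },
    {
      "id": "cooking_group",
      "name": "Healthy cooking group",
      "category": "group_based",
      "availability": "within_municipality",
      "targets": ["eating_pattern", "weight"],
      "description": "Group cooking classes following dietary guidelines."
    },
    {
      "id": "diabetes_cafe",
      "name": "Diabetes cafe",
      "category": "events",
      "availability": "within_municipality",
      "targets": ["problems_with_diabetes", "loneliness"],
      "description": "Informal monthly meet-up for people with diabetes."
    },
    {
      "id": "health_market",
      "name": "Local health market",
      "category": "events",
      "availability": "within_municipality",
      "targets": ["eating_pattern", "perceived_health"],
      "description": "Seasonal market with food and lifestyle stands."
    },
    {
      "id": "community_garden",
      "name": "Community garden day",
      "category": "events",
      "availability": "within_municipality",
      "targets": ["loneliness", "physical_activity"],
      "description": "Shared gardening activity in the neighborhood."
    },
    {
      "id": "dietician",
      "name": "Dietician referral",
      "category": "experts_knowledge_centers",
      "availability": "proximity_to_practice",
      "targets": ["eating_pattern", "weight", "glucose_metabolism"],
      "description": "Personal dietary counseling by a registered dietician."
    },
    {
      "id": "physiotherapist",
      "name": "Physiotherapist referral",
      "category": "experts_knowledge_centers",
      "availability": "proximity_to_practice",
      "targets": ["physical_activity", "pain"],
      "description": "Individual exercise guidance and pain management."
    },
    {
      "id": "addiction_care_team",
      "name": "Addiction care team",
      "category": "experts_knowledge_centers",
      "availability": "within_municipality",
      "targets": ["smoking", "alcohol_consumption"],
      "description": "Specialist support for quitting smoking or drinking."
    },
    {
      "id": "social_worker",
      "name": "Social worker consultation",
      "category": "experts_knowledge_centers",
      "availability": "within_municipality",
      "targets": ["income", "work", "housing"],
      "description": "Help with financial, work, and housing problems."
    },
    {
      "id": "work_reintegration_coach",
      "name": "Work reintegration coach",
      "category": "experts_knowledge_centers",
      "availability": "within_municipality",
      "targets": ["work"],
      "description": "Coaching toward suitable paid or voluntary work."
    },
    {
      "id": "glucose_tracking_app",
      "name": "Glucose tracking app",
      "category": "apps",
      "availability": "nationwide_web",
      "targets": ["glucose_metabolism", "diabetes_management"],
      "description": "Smartphone app for logging glucose and medication."
    },
    {
      "id": "step_counter_app",
      "name": "Step counter app",
      "category": "apps",
      "availability": "nationwide_web",
      "targets": ["physical_activity", "sedentary_behavior"],
      "description": "App that counts daily steps and sets movement goals."
    },
    {
      "id": "meal_planner_app",
      "name": "Meal planner app",
      "category": "apps",
      "availability": "nationwide_web",
      "targets": ["eating_pattern", "weight"],
      "description": "Weekly menus matched to dietary guidelines."
    },
    {
      "id": "relaxation_app",
      "name": "Relaxation exercise app",
      "category": "apps",
      "availability": "nationwide_web",
      "targets": ["perceived_stress", "mental_health"],
      "description": "Short guided breathing and relaxation exercises."
    },
    {
      "id": "quit_smoking_app",
      "name": "Quit smoking app",
      "category": "apps",
      "availability": "nationwide_web",
      "targets": ["smoking"],
      "description": "Daily support program for stopping smoking."
    },
    {
      "id": "step_counter_device",
      "name": "Step counter",
      "category": "devices",
      "availability": "nationwide_web",
      "targets": ["physical_activity", "sedentary_behavior"],
      "description": "Wearable pedometer for daily activity feedback."
    },
    {
      "id": "pulse_meter",
      "name": "Pulse meter",
      "category": "devices",
      "availability": "nationwide_web",
      "targets": ["physical_activity", "blood_pressure"],
      "description": "Heart-rate monitor for safe exercise intensity."
    },
    {
      "id": "home_bp_monitor",
      "name": "Home blood pressure monitor",
      "category": "devices",
      "availability": "nationwide_web",
      "targets": ["blood_pressure"],
      "description": "Validated cuff for self-measuring blood pressure."
    },
    {
      "id": "combined_lifestyle_program",
      "name": "Combined lifestyle intervention",
      "category": "programs",
      "availability": "within_municipality",
      "targets": ["weight", "eating_pattern", "physical_activity"],
      "description": "Two-year reimbursed program on diet, activity, and behavior."
    },
    {
      "id": "cardiac_fitness_program",
      "name": "Cardiovascular fitness program",
      "category": "programs",
      "availability": "proximity_to_practice",
      "targets": ["blood_pressure", "cholesterol", "physical_activity"],
      "description": "Supervised training for cardiovascular risk reduction."
    },
    {
      "id": "debt_counseling_program",
      "name": "Debt counseling program",
      "category": "programs",
      "availability": "within_municipality",
      "targets": ["income"],
      "description": "Municipal program for budgeting and debt restructuring."
    },
    {
      "id": "sleep_stress_program",
      "name": "Sleep and stress program",
      "category": "programs",
      "availability": "nationwide_web",
      "targets": ["perceived_stress", "mental_health"],
      "description": "Online program combining sleep hygiene and stress coping."
    },
    {
      "id": "nutrition_center_site",
      "name": "National nutrition center website",
      "category": "knowledge_platforms",
      "availability": "nationwide_web",
      "targets": ["eating_pattern"],
      "description": "Authoritative dietary guideline information."
    },
    {
      "id": "diabetes_association_portal",
      "name": "Diabetes association portal",
      "category": "knowledge_platforms",
      "availability": "nationwide_web",
      "targets": ["problems_with_diabetes", "diabetes_management"],
      "description": "Patient association knowledge base and forums."
    },
    {
      "id": "kidney_foundation_site",
      "name": "Kidney foundation website",
      "category": "knowledge_platforms",
      "availability": "nationwide_web",
      "targets": ["kidney_function"],
      "description": "Information on protecting kidney function."
    }
  ]
}
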